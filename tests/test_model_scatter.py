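"""Debye bead-model forward scattering, Rg, Stuhrmann prediction, chi^2."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sanskit.composition import composition_from_sequence, match_point
from sanskit.curves import ScatteringCurve, auto_guinier
from sanskit.model_scatter import (
    BeadModel,
    beads_from_structure,
    chi2_to_data,
    debye_intensity,
    model_rg,
    model_rg2,
    predict_stuhrmann,
    sld_centre_offset,
)
from sanskit.synthetic import (
    ComponentSpec,
    SyntheticComplexSpec,
    _bead_positions,
    bead_model_at_contrast,
    packaged_sequence,
)
from tests.conftest import sphere_cloud


def simple_model(positions, b):
    positions = np.atleast_2d(positions)
    n = len(positions)
    return BeadModel(positions, np.asarray(b, dtype=float), np.ones(n),
                     np.array(["x"] * n), np.ones(n))


Q = np.linspace(0.0, 0.5, 40)


class TestDebyeIntensity:
    def test_single_bead_flat(self):
        m = simple_model([[1.0, 2.0, 3.0]], [1.7])
        assert np.allclose(debye_intensity(m, Q), 1.7**2)

    def test_forward_scattering_identity(self):
        rng = np.random.default_rng(2)
        m = simple_model(rng.normal(size=(25, 3)) * 20, rng.normal(size=25))
        i0 = debye_intensity(m, np.array([0.0]))[0]
        assert i0 == pytest.approx(m.b_excess.sum() ** 2, rel=1e-12)

    def test_two_bead_closed_form(self):
        d, b = 17.0, 1.3
        m = simple_model([[0, 0, 0], [d, 0, 0]], [b, b])
        q = Q[1:]
        expect = 2 * b**2 * (1 + np.sin(q * d) / (q * d))
        assert np.allclose(debye_intensity(m, q), expect, rtol=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(30, 3)) * 15
        b = rng.normal(size=30)
        m = simple_model(pos, b)
        R = Rotation.from_euler("zyx", [0.4, -1.2, 2.0]).as_matrix()
        m2 = simple_model(pos @ R.T + np.array([5.0, -3.0, 8.0]), b)
        assert np.allclose(debye_intensity(m, Q), debye_intensity(m2, Q), rtol=1e-10)

    def test_nonnegative_for_mixed_sign_contrasts(self):
        rng = np.random.default_rng(4)
        for seed in range(10):
            r = np.random.default_rng(seed)
            m = simple_model(r.normal(size=(20, 3)) * 25, r.normal(size=20))
            assert np.all(debye_intensity(m, Q) >= -1e-12)

    def test_histogram_method_converges_to_direct(self):
        rng = np.random.default_rng(5)
        m = simple_model(rng.normal(size=(60, 3)) * 30, rng.random(60))
        direct = debye_intensity(m, Q)
        coarse = debye_intensity(m, Q, method="histogram", bin_width=0.5)
        fine = debye_intensity(m, Q, method="histogram", bin_width=0.1)
        assert np.allclose(coarse, direct, rtol=3e-2)
        assert np.allclose(fine, direct, rtol=2e-3)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            BeadModel(np.empty((0, 3)), [], [], [], [])


class TestModelRg:
    def test_two_equal_beads(self):
        m = simple_model([[0, 0, 0], [10.0, 0, 0]], [1.0, 1.0])
        assert model_rg(m) == pytest.approx(5.0)

    def test_uniform_sphere_cloud(self):
        rng = np.random.default_rng(6)
        R = 40.0
        pos = sphere_cloud(rng, 6000, R)
        m = simple_model(pos, np.ones(6000))
        assert model_rg(m) == pytest.approx(np.sqrt(3 / 5) * R, rel=0.01)

    def test_component_at_match_point_invisible(self):
        # beads of component A carry zero contrast: complex Rg == Rg of B
        rng = np.random.default_rng(7)
        pos_a = sphere_cloud(rng, 50, 15, centre=(-30, 0, 0))
        pos_b = sphere_cloud(rng, 50, 20, centre=(40, 0, 0))
        m = BeadModel(np.vstack([pos_a, pos_b]),
                      np.concatenate([np.zeros(50), np.full(50, 0.3)]),
                      np.ones(100), np.array(["A"] * 50 + ["B"] * 50),
                      np.ones(100))
        rg_b = model_rg(m.select("B"))
        assert model_rg(m) == pytest.approx(rg_b, rel=1e-12)

    def test_zero_net_contrast_undefined(self):
        m = simple_model([[0, 0, 0], [10, 0, 0]], [1.0, -1.0])
        with pytest.raises(ValueError, match="match point"):
            model_rg2(m)

    def test_guinier_of_debye_recovers_model_rg(self):
        rng = np.random.default_rng(8)
        pos = sphere_cloud(rng, 400, 35.0)
        m = simple_model(pos, np.ones(400))
        rg = model_rg(m)
        q = np.geomspace(2e-3, 1.3 / rg * 1.6, 200)
        I = debye_intensity(m, q)
        curve = ScatteringCurve(q, I, np.full_like(q, I[0] * 1e-4))
        res = auto_guinier(curve)
        assert res.Rg == pytest.approx(rg, rel=0.02)


def _two_component_spec(deuterate="outer", separation=66.0, n_beads=60):
    inner = composition_from_sequence(packaged_sequence("synthetic_ficd_104-445.fasta"))
    outer = composition_from_sequence(packaged_sequence("synthetic_bip_27-635.fasta"))
    return SyntheticComplexSpec(
        components=(
            ComponentSpec(inner, 0.665 if deuterate == "inner" else 0.0,
                          centres=((-22.0, 0, 0), (22.0, 0, 0)), radius=22.0,
                          n_beads=n_beads, name="inner"),
            ComponentSpec(outer, 0.665 if deuterate == "outer" else 0.0,
                          centres=((-separation, 0, 0), (separation, 0, 0)),
                          radius=27.0, n_beads=n_beads, name="outer"),
        ),
        f_d2o_series=(0.0, 0.2, 0.4, 1.0),
    )


class TestPredictStuhrmann:
    def test_symmetric_complex_has_zero_beta(self):
        spec = _two_component_spec()
        pos, labels = _bead_positions(spec, seed=9)
        res, offset = predict_stuhrmann(
            lambda f: bead_model_at_contrast(spec, f, pos, labels),
            spec.f_d2o_series,
        )
        assert res.model == "linear"
        assert res.beta == 0.0
        assert offset == pytest.approx(0.0, abs=1e-9)

    def test_peripheral_high_contrast_gives_positive_alpha(self):
        # deuterated outer lobes -> higher-contrast material outside
        spec = _two_component_spec(deuterate="outer")
        pos, labels = _bead_positions(spec, seed=10)
        res, _ = predict_stuhrmann(
            lambda f: bead_model_at_contrast(spec, f, pos, labels),
            spec.f_d2o_series,
        )
        assert res.alpha > 0

    def test_alpha_sign_flips_with_label_swap(self):
        pos = None
        alphas = {}
        for lab in ("inner", "outer"):
            spec = _two_component_spec(deuterate=lab)
            pos, labels = _bead_positions(spec, seed=11)
            res, _ = predict_stuhrmann(
                lambda f: bead_model_at_contrast(spec, f, pos, labels),
                spec.f_d2o_series,
            )
            alphas[lab] = res.alpha
        assert alphas["inner"] * alphas["outer"] < 0

    def test_offset_dumbbell_beta_matches_geometry(self):
        # one hydrogenated and one strongly deuterated lobe, offset SLD centre
        comp = composition_from_sequence(packaged_sequence("synthetic_ficd_104-445.fasta"))
        spec = SyntheticComplexSpec(
            components=(
                ComponentSpec(comp, 0.0, centres=((0.0, 0, 0),), radius=20.0,
                              n_beads=120, name="h"),
                ComponentSpec(comp, 0.9, centres=((60.0, 0, 0),), radius=20.0,
                              n_beads=120, name="d"),
            ),
            f_d2o_series=(0.0, 0.1, 0.2, 0.3, 0.9, 1.0),
        )
        pos, labels = _bead_positions(spec, seed=12)
        res, _ = predict_stuhrmann(
            lambda f: bead_model_at_contrast(spec, f, pos, labels),
            spec.f_d2o_series,
        )
        assert res.beta > 0
        # parallel-axis oracle: sqrt(beta)/|drho| equals the direct
        # |SLD centre - COM| distance at each contrast
        for f in (0.0, 0.3):
            m = bead_model_at_contrast(spec, f, pos, labels)
            implied = np.sqrt(res.beta) / abs(m.mean_contrast)
            assert implied == pytest.approx(sld_centre_offset(m), rel=0.05)


class TestChi2:
    def _curve_from_model(self, m, sigma_frac=0.02, seed=0, scale=1.0):
        q = np.geomspace(0.004, 0.25, 80)
        I = debye_intensity(m, q) * scale
        sigma = np.maximum(sigma_frac * I, sigma_frac * I.max() * 1e-3)
        rng = np.random.default_rng(seed)
        noisy = I + rng.normal(0, 1, len(q)) * sigma
        return q, ScatteringCurve(q, noisy, sigma)

    def test_noiseless_self_comparison_is_zero(self):
        rng = np.random.default_rng(13)
        m = simple_model(sphere_cloud(rng, 80, 25), np.ones(80))
        q = np.geomspace(0.004, 0.25, 60)
        I = debye_intensity(m, q)
        curve = ScatteringCurve(q, I, np.full_like(q, 1e-3))
        rep = chi2_to_data(I, curve)
        assert rep.chi2 == pytest.approx(0.0, abs=1e-15)
        assert rep.scale == pytest.approx(1.0)

    def test_expected_chi2_near_one_for_correct_model(self):
        rng = np.random.default_rng(14)
        m = simple_model(sphere_cloud(rng, 80, 25), np.ones(80))
        q = np.geomspace(0.004, 0.25, 80)
        I = debye_intensity(m, q)
        chi2s = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            sigma = 0.02 * I
            noisy = I + r.normal(0, 1, len(q)) * sigma
            curve = ScatteringCurve(q, noisy, sigma)
            chi2s.append(chi2_to_data(I, curve).chi2)
        assert np.mean(chi2s) == pytest.approx(1.0, abs=0.05)

    def test_wrong_geometry_model_rejected(self):
        rng = np.random.default_rng(15)
        sphere = simple_model(sphere_cloud(rng, 80, 25), np.ones(80))
        rod = simple_model(
            np.column_stack([np.linspace(-80, 80, 80), np.zeros(80), np.zeros(80)]),
            np.ones(80),
        )
        q, curve = self._curve_from_model(sphere, sigma_frac=0.02, seed=16)
        i_rod = debye_intensity(rod, q)
        assert chi2_to_data(i_rod, curve).chi2 > 5.0


class TestBeadsFromStructure:
    def _poly_gly_pdb(self, tmp_path, n=12):
        lines = []
        for i in range(n):
            x = 1.5 * i
            lines.append(
                f"ATOM  {i + 1:5d}  CA  GLY A{i + 1:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            )
        p = tmp_path / "polygly.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        return str(p)

    def test_bead_count_equals_residue_count(self, tmp_path):
        from sanskit.structures import parse_structure

        path = self._poly_gly_pdb(tmp_path, n=12)
        st = parse_structure(path)
        model = beads_from_structure(st, {"A": 0.0}, f_D2O=0.0)
        assert len(model) == 12

    def test_match_point_solvent_hides_beads(self, tmp_path):
        from sanskit.structures import parse_structure

        gly = composition_from_sequence("G", add_termini=False)
        f_match = match_point([(gly, 0.0)]).f_D2O
        st = parse_structure(self._poly_gly_pdb(tmp_path))
        model = beads_from_structure(st, {"A": 0.0}, f_D2O=f_match)
        assert np.allclose(model.b_excess, 0.0, atol=1e-12)

    def test_labelling_changes_contrast_not_positions(self, tmp_path):
        from sanskit.structures import parse_structure

        st = parse_structure(self._poly_gly_pdb(tmp_path))
        m0 = beads_from_structure(st, {"A": 0.0}, f_D2O=0.4)
        m1 = beads_from_structure(st, {"A": 0.8}, f_D2O=0.4)
        assert np.array_equal(m0.positions, m1.positions)
        assert np.all(m1.b_excess > m0.b_excess)

    def test_unassigned_chain_rejected(self, tmp_path):
        from sanskit.structures import parse_structure

        st = parse_structure(self._poly_gly_pdb(tmp_path))
        with pytest.raises(ValueError, match="labelling"):
            beads_from_structure(st, {"B": 0.0}, f_D2O=0.0)
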