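"""Sequence -> composition -> SLD / match-point machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sanskit.composition import (
    AVOGADRO,
    Composition,
    LabellingState,
    composition_from_sequence,
    infer_deuteration,
    match_point,
    mw_from_forward_scattering,
    protein_sld,
    solvent_sld,
    theoretical_i0_per_c,
)

# Sears scattering lengths restated here as the independent oracle's constants
B_H, B_D, B_C, B_N, B_O, B_S = -3.7390, 6.671, 6.6460, 9.36, 5.803, 2.847  # fm


class TestCompositionFromSequence:
    def test_single_glycine_is_free_amino_acid(self):
        comp = composition_from_sequence("G")
        assert comp.atom_counts["C"] == 2
        assert comp.atom_counts["H"] == 5
        assert comp.atom_counts["N"] == 1
        assert comp.atom_counts["O"] == 2

    def test_peptide_bond_condensation(self):
        gg = composition_from_sequence("GG")
        g = composition_from_sequence("G")
        # two glycines minus one water
        assert gg.atom_counts["C"] == 2 * g.atom_counts["C"]
        assert gg.atom_counts["H"] == 2 * g.atom_counts["H"] - 2
        assert gg.atom_counts["O"] == 2 * g.atom_counts["O"] - 1
        assert gg.atom_counts["N"] == 2 * g.atom_counts["N"]

    def test_labile_count_matches_manual_tally(self):
        # residue-by-residue hand count of N/O/S-bound hydrogens, pH ~7
        # backbone NH = 1 each; side chains: M 0, K +3 (ammonium), L 0,
        # S +1, V 0, A 0, R +5 (guanidinium), T +1
        seq = "MKLSVAARST"
        side = {"M": 0, "K": 3, "L": 0, "S": 1, "V": 0, "A": 0, "R": 5, "T": 1}
        manual = sum(1 + side[ch] for ch in seq) + 2  # + terminal NH/OH pair
        comp = composition_from_sequence(seq)
        assert comp.n_labile_H == manual

    def test_unknown_residue_letter_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            composition_from_sequence("GAXG")

    def test_concatenation_equals_sum_minus_water(self):
        a = composition_from_sequence("ACDE", add_termini=False)
        b = composition_from_sequence("FGHI", add_termini=False)
        ab = composition_from_sequence("ACDEFGHI", add_termini=False)
        combined = a + b
        for el in ab.atom_counts:
            assert ab.atom_counts[el] == pytest.approx(combined.atom_counts[el])
        assert ab.volume == pytest.approx(combined.volume)

    def test_invariant_checks(self):
        with pytest.raises(ValueError, match="volume"):
            Composition({"C": 1, "H": 1}, 1, 0, 0.0, 10.0)
        with pytest.raises(ValueError, match="hydrogens"):
            Composition({"C": 1, "H": 3}, 1, 1, 10.0, 10.0)


class TestSolventSld:
    def test_pure_h2o_against_atomic_sum(self):
        v_h2o = 18.0153 / (0.99821 * 0.602214076)  # A^3 at 20 degC
        rho = (2 * B_H + B_O) * 1e-5 / v_h2o
        assert solvent_sld(0.0) == pytest.approx(rho, rel=1e-12)

    def test_pure_d2o_against_atomic_sum(self):
        v_d2o = 20.0276 / (1.1050 * 0.602214076)
        rho = (2 * B_D + B_O) * 1e-5 / v_d2o
        assert solvent_sld(1.0) == pytest.approx(rho, rel=1e-12)

    def test_midpoint_is_linear(self):
        assert solvent_sld(0.5) == pytest.approx(
            0.5 * (solvent_sld(0.0) + solvent_sld(1.0))
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            solvent_sld(1.2)


class TestProteinSld:
    def setup_method(self):
        self.comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY")

    def test_hydrogenated_sld_against_brute_force_sum(self):
        # independent oracle: direct sum b over all atoms / volume
        c = self.comp
        total_fm = (
            c.atom_counts["C"] * B_C + c.atom_counts["N"] * B_N
            + c.atom_counts["O"] * B_O + c.atom_counts.get("S", 0) * B_S
            + c.atom_counts["H"] * B_H
        )
        rho = total_fm * 1e-5 / c.volume
        got = protein_sld(c, LabellingState(0.0, 0.95, 0.0))
        assert got.rho == pytest.approx(rho, rel=1e-12)
        assert got.delta_rho == pytest.approx(rho - solvent_sld(0.0), rel=1e-12)

    def test_full_deuteration_shift(self):
        c = self.comp
        r0 = protein_sld(c, LabellingState(0.0, 0.95, 0.0)).rho
        r1 = protein_sld(c, LabellingState(1.0, 0.95, 0.0)).rho
        expected = c.n_nonlabile_H * (B_D - B_H) * 1e-5 / c.volume
        assert r1 - r0 == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("var", ["f_deut", "f_D2O"])
    def test_rho_affine_in_labelling_variables(self, var):
        vals = [0.0, 0.35, 0.7]
        rhos = []
        for v in vals:
            lab = LabellingState(**{var: v})
            rhos.append(protein_sld(self.comp, lab).rho)
        # collinear: midpoint test at unequal spacing
        slope1 = (rhos[1] - rhos[0]) / (vals[1] - vals[0])
        slope2 = (rhos[2] - rhos[1]) / (vals[2] - vals[1])
        assert slope1 == pytest.approx(slope2, rel=1e-9)


SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40)


class TestMatchPoint:
    def test_hydrogenated_protein_in_40_45_band(self):
        comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 2 + "ACDEFGHIKL")
        res = match_point([(comp, 0.0)])
        assert res.in_range
        assert 0.40 <= res.f_D2O <= 0.45

    def test_degenerate_slope_flagged(self):
        # a composition with enough labile H that its SLD tracks the solvent:
        # engineer by zeroing the volume-driven slope via a tiny volume
        comp = composition_from_sequence("G" * 10)
        # solve for labile_exchange that makes the slope vanish is impossible
        # within [0,1] for a real protein; instead test the degenerate branch
        # with a fabricated composition whose slope terms cancel
        from sanskit.composition import SCATTERING_LENGTH_FM, _FM_TO_A, solvent_sld

        d_solv = solvent_sld(1.0) - solvent_sld(0.0)
        b_hd = (SCATTERING_LENGTH_FM["D"] - SCATTERING_LENGTH_FM["H"]) * _FM_TO_A
        n_lab = 10.0
        vol = n_lab * 1.0 * b_hd / d_solv  # slope-cancelling volume
        fake = Composition({"C": 5, "H": 10}, n_lab, 0.0, vol, 100.0)
        res = match_point([(fake, 0.0)], labile_exchange=1.0)
        assert res.degenerate

    @settings(max_examples=25, deadline=None)
    @given(seq_a=SEQ, seq_b=SEQ, fd_a=st.floats(0, 1), fd_b=st.floats(0, 1))
    def test_complex_cmp_between_component_cmps(self, seq_a, seq_b, fd_a, fd_b):
        ca = composition_from_sequence(seq_a)
        cb = composition_from_sequence(seq_b)
        ra = match_point([(ca, fd_a)])
        rb = match_point([(cb, fd_b)])
        rab = match_point([(ca, fd_a), (cb, fd_b)])
        lo, hi = sorted([ra.f_D2O, rb.f_D2O])
        assert lo - 1e-9 <= rab.f_D2O <= hi + 1e-9

    def test_match_point_monotone_in_deuteration(self):
        comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY")
        mps = [match_point([(comp, fd)]).f_D2O for fd in (0.0, 0.3, 0.6, 0.9)]
        assert np.all(np.diff(mps) > 0)

    def test_infer_deuteration_round_trip(self):
        ch = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY")
        cd = composition_from_sequence("MKLSVAARSTWYNQ")
        for fd in (0.1, 0.5, 0.9):
            cmp_th = match_point([(ch, 0.0), (cd, fd)]).f_D2O
            got = infer_deuteration(ch, cd, cmp_th)
            assert got == pytest.approx(fd, abs=1e-10)

    def test_out_of_range_root_rejected(self):
        ch = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY")
        with pytest.raises(ValueError, match="outside"):
            infer_deuteration(ch, ch, 0.95)


class TestMolecularWeight:
    def setup_method(self):
        self.comps = [
            (composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 5), 0.0),
            (composition_from_sequence("MKLSVAARST" * 8), 0.7),
        ]

    def test_round_trip_through_forward_direction(self):
        mass = sum(c.mass for c, _ in self.comps)
        i0c = theoretical_i0_per_c(self.comps, f_D2O=0.0)
        got = mw_from_forward_scattering(i0c, self.comps, f_D2O=0.0)
        assert got == pytest.approx(mass, rel=1e-10)

    def test_two_to_two_is_twice_one_to_one(self):
        i0c_11 = theoretical_i0_per_c(self.comps, 0.0, stoichiometry=[1, 1])
        mw_as_22 = mw_from_forward_scattering(
            2 * i0c_11, self.comps, 0.0, stoichiometry=[2, 2]
        )
        mw_as_11 = mw_from_forward_scattering(
            i0c_11, self.comps, 0.0, stoichiometry=[1, 1]
        )
        assert mw_as_22 == pytest.approx(2 * mw_as_11, rel=1e-10)

    def test_match_point_measurement_rejected(self):
        cmp_th = match_point(self.comps).f_D2O
        with pytest.raises(ValueError, match="match point"):
            mw_from_forward_scattering(1.0, self.comps, cmp_th)

    def test_bead_model_mw_consistent_with_composition(self):
        # oracle: Debye forward scattering I(0) = (sum delta_b)^2
        from sanskit.synthetic import (
            ComponentSpec,
            SyntheticComplexSpec,
            _bead_positions,
            bead_model_at_contrast,
        )

        comps = tuple(
            ComponentSpec(c, fd, centres=((40.0 * i, 0, 0),), radius=18.0,
                          n_beads=50, name=f"c{i}")
            for i, (c, fd) in enumerate(self.comps)
        )
        spec = SyntheticComplexSpec(components=comps, f_d2o_series=(0.0,))
        pos, labels = _bead_positions(spec, seed=11)
        model = bead_model_at_contrast(spec, 0.0, pos, labels)
        mass = sum(c.mass for c, _ in self.comps)
        i0_per_c = (model.b_excess.sum() * 1e-8) ** 2 * AVOGADRO / mass
        got = mw_from_forward_scattering(i0_per_c, self.comps, 0.0)
        assert got == pytest.approx(mass, rel=0.05)
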