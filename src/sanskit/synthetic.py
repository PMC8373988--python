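"""Seeded generators emulating every experimental input of the pipeline.

Each generator returns a ``(data, truth)`` pair: recovery tests consume only
the data and compare estimates against the attached ground truth.  All
randomness flows from a single integer seed.

The default SANS geometry emulates a 2:2 hetero-complex with the labelled
enzyme dimer on the inside and two larger substrate lobes flanking it, so
that Stuhrmann sign conventions (alpha > 0 when the high-contrast component
is peripheral; beta > 0 when the SLD centre is displaced from the centre of
mass) can be exercised in both directions by swapping the deuterated
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .composition import (
    Composition,
    LabellingState,
    composition_from_sequence,
    match_point,
    solvent_sld,
    _total_b,
)
from .curves import ScatteringCurve
from .kinetics import ProgressCurve, simulate_mm_progress
from .binding import BliTrace
from .model_scatter import BeadModel, debye_intensity, model_rg2, predict_stuhrmann

__all__ = [
    "ComponentSpec",
    "SyntheticComplexSpec",
    "SansTruth",
    "generate_sans_series",
    "bead_model_at_contrast",
    "generate_fp_assay",
    "generate_bli_traces",
    "generate_dsf_curve",
    "default_complex_spec",
    "packaged_sequence",
]


def packaged_sequence(name: str) -> str:
    """Sequence string from a FASTA bundled with the package (data/)."""
    from importlib import resources

    text = resources.files("sanskit.data").joinpath(name).read_text()
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith(">")]
    return "".join(lines)


@dataclass(frozen=True)
class ComponentSpec:
    """One component of the synthetic complex: composition, label, placement."""

    composition: Composition
    f_deut: float
    centres: tuple[tuple[float, float, float], ...]  # one per copy
    radius: float  # A, per-copy spherical bead cloud
    n_beads: int = 80
    name: str = "component"


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Study design for a synthetic contrast-variation series."""

    components: tuple[ComponentSpec, ...]
    f_d2o_series: tuple[float, ...]
    conc: float = 5.0  # mg/ml
    labile_exchange: float = 0.95
    noise_a: float = 0.01  # sigma(q) = a * sqrt(I + b)
    noise_b: float = 1e-3
    # geometric grid: dense at low q where the Guinier region of a ~60 A
    # particle lives, sparser towards the wide-angle end
    q_grid: tuple[float, ...] = tuple(np.geomspace(0.0035, 0.30, 140))

    def __post_init__(self) -> None:
        if len(set(self.f_d2o_series)) != len(self.f_d2o_series):
            raise ValueError("f_D2O values must be distinct")
        if self.noise_a < 0 or self.noise_b <= 0:
            raise ValueError("noise model requires a >= 0 and b > 0")


@dataclass(frozen=True)
class SansTruth:
    """Ground truth attached to a generated contrast series."""

    cmp: float
    rg2_by_f: dict[float, float]
    stuhrmann: tuple[float, float, float]  # Rm2, alpha, beta
    mass: float
    i0_by_f: dict[float, float]


def default_complex_spec(
    deuterate: str = "outer",
    f_deut: float = 0.665,
    f_d2o_series: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_beads: int = 80,
) -> SyntheticComplexSpec:
    """2:2 complex: inner enzyme dimer flanked by two outer substrate lobes.

    ``deuterate`` picks which component carries the non-labile deuteration
    (the other stays hydrogenated), mirroring the two oppositely labelled
    complexes of a contrast-variation experiment.
    """
    inner_seq = packaged_sequence("synthetic_ficd_104-445.fasta")
    outer_seq = packaged_sequence("synthetic_bip_27-635.fasta")
    inner = composition_from_sequence(inner_seq, name="inner")
    outer = composition_from_sequence(outer_seq, name="outer", n_amp=1)
    fd_inner = f_deut if deuterate == "inner" else 0.0
    fd_outer = f_deut if deuterate == "outer" else 0.0
    comps = (
        ComponentSpec(inner, fd_inner, centres=((-22.0, 0, 0), (22.0, 0, 0)),
                      radius=22.0, n_beads=n_beads, name="inner"),
        ComponentSpec(outer, fd_outer, centres=((-66.0, 0, 0), (66.0, 0, 0)),
                      radius=27.0, n_beads=n_beads, name="outer"),
    )
    return SyntheticComplexSpec(components=comps, f_d2o_series=tuple(f_d2o_series))


def _sphere_cloud(rng: np.random.Generator, n: int, radius: float,
                  centre: np.ndarray) -> np.ndarray:
    u = rng.random(n)
    r = radius * u ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return centre + r[:, None] * v


def _bead_positions(spec: SyntheticComplexSpec, seed: int):
    rng = np.random.default_rng(seed)
    positions, labels, copies = [], [], []
    for comp in spec.components:
        for c in comp.centres:
            positions.append(_sphere_cloud(rng, comp.n_beads, comp.radius,
                                           np.asarray(c, dtype=float)))
            labels.extend([comp.name] * comp.n_beads)
    return np.vstack(positions), np.array(labels)


def bead_model_at_contrast(
    spec: SyntheticComplexSpec,
    f_d2o: float,
    positions: np.ndarray,
    labels: np.ndarray,
) -> BeadModel:
    """Bead model of the spec's complex at one solvent composition."""
    rho_s = solvent_sld(f_d2o)
    b_exc = np.empty(len(positions))
    vol = np.empty(len(positions))
    mass = np.empty(len(positions))
    for comp in spec.components:
        m = labels == comp.name
        lab = LabellingState(comp.f_deut, spec.labile_exchange, f_d2o)
        n_copies = len(comp.centres)
        per_bead = 1.0 / comp.n_beads  # composition split over one copy's beads
        b_total = _total_b(comp.composition, lab)
        b_exc[m] = (b_total - rho_s * comp.composition.volume) * per_bead
        vol[m] = comp.composition.volume * per_bead
        mass[m] = comp.composition.mass * per_bead
        assert m.sum() == n_copies * comp.n_beads
    return BeadModel(positions, b_exc, vol, labels, mass)


def generate_sans_series(
    spec: SyntheticComplexSpec, seed: int
) -> tuple[list[ScatteringCurve], SansTruth]:
    """Contrast series of noisy Debye curves plus the generating truth.

    Intensities are scaled by concentration so sqrt(I(0)/c) is proportional
    to the complex's total excess scattering length; Gaussian noise has the
    counting-statistics-like sigma(q) = a * sqrt(I(q) + b).
    """
    positions, labels = _bead_positions(spec, seed)
    noise_rng = np.random.default_rng(seed + 1)
    q = np.asarray(spec.q_grid)
    curves: list[ScatteringCurve] = []
    rg2_by_f: dict[float, float] = {}
    i0_by_f: dict[float, float] = {}
    pairs = []
    for comp in spec.components:
        pairs.append((comp.composition, comp.f_deut))
    stoich = [len(comp.centres) for comp in spec.components]
    cmp_theory = match_point(pairs, stoichiometry=stoich,
                             labile_exchange=spec.labile_exchange)
    models = {}
    all_zero = True
    for f in spec.f_d2o_series:
        model = bead_model_at_contrast(spec, f, positions, labels)
        models[f] = model
        if abs(model.b_excess.sum()) > 1e-9:
            all_zero = False
    if all_zero:
        raise ValueError("all contrasts vanish for this spec")
    for f in spec.f_d2o_series:
        model = models[f]
        intensity = debye_intensity(model, q) * spec.conc
        sigma = spec.noise_a * np.sqrt(np.abs(intensity) + spec.noise_b)
        noisy = intensity + noise_rng.normal(0.0, 1.0, len(q)) * sigma
        curves.append(ScatteringCurve(q=q, I=noisy, sigma=np.maximum(sigma, 1e-12),
                                      f_D2O=f, conc=spec.conc,
                                      label="+".join(c.name for c in spec.components
                                                     if c.f_deut > 0) or "h"))
        try:
            rg2_by_f[f] = model_rg2(model)
        except ValueError:
            rg2_by_f[f] = np.nan
        i0_by_f[f] = float(model.b_excess.sum() ** 2 * spec.conc)
    if len(spec.f_d2o_series) >= 4:
        stuh, _ = predict_stuhrmann(
            lambda f: bead_model_at_contrast(spec, f, positions, labels),
            spec.f_d2o_series,
        )
        stuh_truth = (stuh.Rm2, stuh.alpha, stuh.beta)
    else:
        stuh_truth = (float("nan"), float("nan"), float("nan"))
    mass = sum(len(c.centres) * c.composition.mass for c in spec.components)
    truth = SansTruth(cmp=cmp_theory.f_D2O, rg2_by_f=rg2_by_f,
                      stuhrmann=stuh_truth, mass=mass, i0_by_f=i0_by_f)
    return curves, truth


def generate_fp_assay(
    kcat: float,
    km: float,
    E0: float,
    S0: float,
    dmfp_total: float,
    noise_sigma: float,
    seed: int,
    t_grid: np.ndarray | None = None,
    mfp0: float = 200.0,
) -> tuple[ProgressCurve, dict]:
    """Noisy mFP deAMPylation time course plus the generating truth.

    The Michaelis-Menten progress curve is converted to polarisation via the
    inverse of the endpoint calibration: mFP(t) = mfp0 - dmfp_total *
    converted(t)/S0, with Gaussian noise on the signal.
    """
    if t_grid is None:
        t_total = 0.4 * (km + S0) / (kcat * E0)  # reaches well past 10% conversion
        t_grid = np.linspace(0.0, t_total, 120)
    clean = simulate_mm_progress(kcat, km, E0, S0, t_grid)
    rng = np.random.default_rng(seed)
    mfp = mfp0 - dmfp_total * clean.signal / S0
    if noise_sigma > 0:
        mfp = mfp + rng.normal(0.0, noise_sigma, len(mfp))
    curve = ProgressCurve(t=t_grid, signal=mfp, E0=E0, S0=S0, units="mFP",
                          dmfp_total=dmfp_total)
    v0_true = kcat * E0 * S0 / (km + S0)
    return curve, {"kcat": kcat, "km": km, "v0": v0_true,
                   "efficiency": kcat / (km + S0)}


def generate_bli_traces(
    kon: float,
    koff: float,
    bmax: float,
    conc_series: Sequence[float],
    t_assoc: float = 50.0,
    t_dissoc: float = 50.0,
    dt: float = 0.1,
    noise_sigma: float = 0.0,
    seed: int = 0,
    two_phase: tuple[float, float, float] | None = None,
    loading: float = 1.0,
) -> tuple[list[BliTrace], dict]:
    """One-phase (optionally two-phase) association-dissociation traces.

    ``two_phase=(fast_fraction, k_fast, k_slow)`` replaces the dissociation
    decay with a biphasic mixture.  Returns traces (association then
    dissociation per concentration) and the truth record.
    """
    rng = np.random.default_rng(seed)
    traces: list[BliTrace] = []
    ta = np.arange(0.0, t_assoc + dt / 2, dt)
    ta[0] = 1e-9  # keep strictly increasing from ~0
    td = np.arange(0.0, t_dissoc + dt / 2, dt)
    td[0] = 1e-9
    kd = koff / kon
    for c in conc_series:
        req = bmax * c / (kd + c)
        kobs = kon * c + koff
        ra = req * (1.0 - np.exp(-kobs * ta))
        r_end = ra[-1]
        if two_phase is None:
            rd = r_end * np.exp(-koff * td)
        else:
            ffast, kf, ks = two_phase
            rd = r_end * (ffast * np.exp(-kf * td) + (1 - ffast) * np.exp(-ks * td))
        if noise_sigma > 0:
            ra = ra + rng.normal(0.0, noise_sigma * max(bmax, 1e-9), len(ta))
            rd = rd + rng.normal(0.0, noise_sigma * max(bmax, 1e-9), len(td))
        traces.append(BliTrace(ta.copy(), ra, "association", c, loading))
        traces.append(BliTrace(td.copy(), rd, "dissociation", c, loading))
    truth = {"kon": kon, "koff": koff, "bmax": bmax, "kd": kd,
             "two_phase": two_phase}
    return traces, truth


def generate_dsf_curve(
    tm: float,
    width: float,
    amplitude: float,
    noise_sigma: float,
    seed: int,
    t_range: tuple[float, float] = (25.0, 90.0),
    dt: float = 0.5,
    quench_rate: float = 0.0,
    baseline: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sigmoidal melt curve with optional post-transition dye quench.

    Returns (temperature, rfu, truth).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    T = np.arange(t_range[0], t_range[1] + dt / 2, dt)
    rfu = baseline + amplitude / (1.0 + np.exp(-(T - tm) / width))
    if quench_rate > 0:
        onset = tm + 3.0 * width
        rfu = rfu - quench_rate * np.clip(T - onset, 0.0, None) * amplitude
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        rfu = rfu + rng.normal(0.0, noise_sigma * amplitude, len(T))
    return T, rfu, {"tm": tm, "width": width, "amplitude": amplitude}
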