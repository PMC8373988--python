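"""Forward SANS observables from coarse-grained bead models.

A :class:`BeadModel` carries one scatterer per residue (or per synthetic
bead) with an excess scattering length Delta_b_i = b_i - rho_solvent * V_i.
From it the Debye equation gives the orientationally averaged intensity

    I(q) = sum_ij Delta_b_i Delta_b_j sin(q r_ij) / (q r_ij),

the contrast-weighted radius of gyration follows from the Delta_b-weighted
second moment, and evaluating the model across several solvent contrasts
yields predicted Stuhrmann coefficients.  A reduced chi^2 against measured
curves (with analytically optimal scale and optional flat background)
quantifies model-data agreement.

No hydration shell is modelled; atomistic predictors that include one
(e.g. CRYSON) differ in absolute Rg by ~1-2%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .composition import Composition, LabellingState, _total_b, solvent_sld
from .curves import ScatteringCurve, StuhrmannResult

__all__ = [
    "BeadModel",
    "Chi2Report",
    "debye_intensity",
    "model_rg",
    "model_rg2",
    "sld_centre_offset",
    "predict_stuhrmann",
    "chi2_to_data",
    "beads_from_structure",
]


@dataclass
class BeadModel:
    """Coarse-grained scatterer set: positions (A), excess lengths, volumes."""

    positions: np.ndarray  # (N, 3)
    b_excess: np.ndarray  # (N,) A
    volume: np.ndarray  # (N,) A^3
    component: np.ndarray  # (N,) labels
    mass: np.ndarray  # (N,) Da

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        if n < 1 or self.positions.shape[1] != 3:
            raise ValueError("positions must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        self.b_excess = np.asarray(self.b_excess, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.component = np.asarray(self.component)
        self.mass = np.asarray(self.mass, dtype=float)
        for name in ("b_excess", "volume", "component", "mass"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of beads")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, component: str) -> "BeadModel":
        m = self.component == component
        if not m.any():
            raise ValueError(f"no beads with component label {component!r}")
        return BeadModel(self.positions[m], self.b_excess[m], self.volume[m],
                         self.component[m], self.mass[m])

    @property
    def mean_contrast(self) -> float:
        """Volume-average excess SLD of the whole model (A^-2)."""
        return float(self.b_excess.sum() / self.volume.sum())


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the series value 1 - x^2/6 below 1e-4 for stability
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = np.sin(xs) / xs
    out[small] = 1.0 - x[small] ** 2 / 6.0
    return out


def debye_intensity(
    model: BeadModel,
    q_grid: np.ndarray,
    method: str = "direct",
    bin_width: float = 0.5,
) -> np.ndarray:
    """Debye-equation intensity of the model on a q grid (q >= 0, A^-1).

    ``method="direct"`` performs the exact O(N^2) pair sum;
    ``method="histogram"`` bins pair distances (default 0.5 A) first, which
    is faster for large N at a small discretisation cost.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if len(model) == 0:
        raise ValueError("empty model")
    b = model.b_excess
    self_term = float(np.sum(b**2))
    if len(model) == 1:
        return np.full_like(q, self_term)
    r = pdist(model.positions)
    bb = _pair_products(b)
    if method == "histogram":
        nbins = max(1, int(np.ceil(r.max() / bin_width)))
        hist, edges = np.histogram(r, bins=nbins, range=(0, nbins * bin_width),
                                   weights=bb)
        centers = 0.5 * (edges[:-1] + edges[1:])
        cross = np.array([np.sum(hist * _sinc(qi * centers)) for qi in q])
    elif method == "direct":
        cross = np.array([np.sum(bb * _sinc(qi * r)) for qi in q])
    else:
        raise ValueError(f"unknown method {method!r}")
    return self_term + 2.0 * cross


def _pair_products(b: np.ndarray) -> np.ndarray:
    """b_i * b_j for i < j in pdist ordering."""
    n = len(b)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        m = n - 1 - i
        out[k:k + m] = b[i] * b[i + 1:]
        k += m
    return out


def model_rg2(model: BeadModel, weights: str = "contrast") -> float:
    """Signed Rg^2 (A^2): sum w_i |r_i - r_w|^2 / sum w_i.

    ``weights="contrast"`` uses the excess scattering lengths (may yield a
    negative Rg^2 between component match points); ``weights="mass"`` gives
    the geometric/COM variant.  Raises ``ValueError`` when the net weight
    vanishes (a complex observed at its own match point).
    """
    w = model.b_excess if weights == "contrast" else model.mass
    total = w.sum()
    if abs(total) < 1e-12 * np.abs(w).sum() or np.abs(w).sum() == 0:
        raise ValueError("net weight ~ 0: Rg undefined at the match point")
    centre = (w[:, None] * model.positions).sum(axis=0) / total
    d2 = np.sum((model.positions - centre) ** 2, axis=1)
    return float(np.sum(w * d2) / total)


def model_rg(model: BeadModel, weights: str = "contrast") -> float:
    """Contrast-weighted (default) or mass-weighted radius of gyration (A)."""
    rg2 = model_rg2(model, weights)
    if rg2 < 0:
        raise ValueError(f"negative Rg^2 = {rg2:.4g}: contrast-weighted Rg undefined")
    return float(np.sqrt(rg2))


def sld_centre_offset(model: BeadModel) -> float:
    """|contrast-weighted centroid - mass centroid| of the model (A)."""
    b = model.b_excess
    m = model.mass
    cb = (b[:, None] * model.positions).sum(axis=0) / b.sum()
    cm = (m[:, None] * model.positions).sum(axis=0) / m.sum()
    return float(np.linalg.norm(cb - cm))


def predict_stuhrmann(
    model_at_contrast: Callable[[float], BeadModel],
    f_d2o_series: Sequence[float],
    linear_margin: float = 0.02,
) -> tuple[StuhrmannResult, float]:
    """Stuhrmann coefficients predicted from a bead model across contrasts.

    ``model_at_contrast(f_D2O)`` must rebuild the model at each solvent
    composition.  Returns the fitted :class:`StuhrmannResult` plus the
    SLD-centre-to-COM distance implied by beta, sqrt(beta)*|1/drho| evaluated
    at the smallest |1/drho| (i.e. the highest contrast supplied).
    """
    if len(f_d2o_series) < 4:
        raise ValueError("need >= 4 contrasts to resolve the quadratic term")
    rg2s = []
    drhos = []
    for f in f_d2o_series:
        m = model_at_contrast(f)
        rg2s.append(model_rg2(m))
        drhos.append(m.mean_contrast)
    drhos_arr = np.asarray(drhos)
    # fit on Rg^2 directly: values may legitimately be negative near a match point
    y = np.asarray(rg2s)
    res = _stuhrmann_fit_rg2(y, drhos_arr, linear_margin)
    dmax = np.min(np.abs(1.0 / drhos_arr))
    implied_offset = float(np.sqrt(max(res.beta, 0.0)) * dmax)
    return res, implied_offset


def _stuhrmann_fit_rg2(rg2: np.ndarray, drho: np.ndarray, margin: float) -> StuhrmannResult:
    from .curves import _ols_design  # shared weighted-LS helper

    x = 1.0 / drho
    w = np.ones_like(x)
    Xl = np.column_stack([np.ones_like(x), x])
    bl, cl, r2l = _ols_design(Xl, rg2, w)
    Xq = np.column_stack([np.ones_like(x), x, -(x**2)])
    bq, cq, r2q = _ols_design(Xq, rg2, w)
    if r2q - r2l < margin:
        return StuhrmannResult(float(bl[0]), float(bl[1]), 0.0,
                               float(np.sqrt(max(cl[0, 0], 0))),
                               float(np.sqrt(max(cl[1, 1], 0))), 0.0,
                               "linear", r2l, r2q)
    return StuhrmannResult(float(bq[0]), float(bq[1]), float(bq[2]),
                           float(np.sqrt(max(cq[0, 0], 0))),
                           float(np.sqrt(max(cq[1, 1], 0))),
                           float(np.sqrt(max(cq[2, 2], 0))),
                           "quadratic", r2l, r2q)


@dataclass(frozen=True)
class Chi2Report:
    """Reduced chi^2 of a model curve against one measurement."""

    chi2: float
    scale: float
    background: float
    n: int

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def chi2_to_data(
    i_model: np.ndarray,
    curve: ScatteringCurve,
    fit_background: bool = False,
) -> Chi2Report:
    """Reduced chi^2 between a model intensity (on the curve's q grid) and data.

    chi^2 = 1/(N - p) sum ((s*I_model + b - I_exp) / sigma)^2 with the scale
    s (and optional background b) solved analytically by weighted least
    squares; p = 1 without background, 2 with.
    """
    im = np.asarray(i_model, dtype=float)
    if len(im) != len(curve.q):
        raise ValueError("model intensity must be evaluated on the curve's q grid")
    if len(im) < 3:
        raise ValueError("need >= 3 points")
    w = 1.0 / curve.sigma**2
    if fit_background:
        X = np.column_stack([im, np.ones_like(im)])
        A = (X * w[:, None]).T @ X
        rhs = (X * w[:, None]).T @ curve.I
        s, b = np.linalg.solve(A, rhs)
        dof = len(im) - 2
    else:
        s = float(np.sum(w * im * curve.I) / np.sum(w * im**2))
        b = 0.0
        dof = len(im) - 1
    resid = (s * im + b - curve.I) / curve.sigma
    chi2 = float(np.sum(resid**2) / dof)
    return Chi2Report(chi2=chi2, scale=float(s), background=float(b), n=len(im))


def beads_from_structure(
    structure,
    labelling: dict[str, LabellingState | float],
    f_D2O: float,
    residue_compositions: dict[str, Composition] | None = None,
) -> BeadModel:
    """One bead per residue at the Calpha position.

    ``labelling`` maps chain id -> LabellingState (or plain f_deut); every
    chain present must be assigned.  Bead scattering length and volume come
    from the residue composition tables, with the excess length subtracting
    the solvent SLD times the residue volume.
    """
    from .composition import _RESIDUES, _ATOMIC_MASS
    from .structures import THREE_TO_ONE, StructureModel

    if not isinstance(structure, StructureModel):
        raise TypeError("structure must be a StructureModel")
    rho_s = solvent_sld(f_D2O)
    positions, b_exc, vols, comps, masses = [], [], [], [], []
    for chain, resnum, resname, xyz in structure.iter_ca():
        if chain not in labelling:
            raise ValueError(f"chain {chain!r} has no labelling assignment")
        lab = labelling[chain]
        if not isinstance(lab, LabellingState):
            lab = LabellingState(f_deut=float(lab), f_D2O=f_D2O)
        elif lab.f_D2O != f_D2O:
            lab = LabellingState(lab.f_deut, lab.labile_exchange, f_D2O)
        one = THREE_TO_ONE.get(resname)
        if one is None:
            continue  # non-standard residue: skip (ligands handled separately)
        from .composition import composition_from_sequence
        comp = composition_from_sequence(one, add_termini=False)
        b = _total_b(comp, lab)
        positions.append(xyz)
        b_exc.append(b - rho_s * comp.volume)
        vols.append(comp.volume)
        comps.append(chain)
        masses.append(comp.mass)
    if not positions:
        raise ValueError("no Calpha beads could be built")
    return BeadModel(np.array(positions), np.array(b_exc), np.array(vols),
                     np.array(comps), np.array(masses))
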