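"""Bio-layer interferometry binding models.

Four analyses for label-free association/dissociation traces:

* a global one-phase association-dissociation fit across an analyte dilution
  series (shared kon, koff, Bmax), R_assoc(t) = Req(C)(1 - e^{-(kon C + koff)t})
  and R_dissoc(t) = R_end e^{-koff t};
* a two-phase exponential dissociation decay with the final plateau fixed at
  zero, R(t) = A1 e^{-k1 t} + A2 e^{-k2 t};
* a steady-state one-site fit Req(C) = Bmax C / (KD + C) to equilibrium
  responses averaged over a fixed late-association window; and
* the detectability argument giving a KD lower bound for an interaction
  showing no signal at the highest tested analyte concentration.

Exponential fits are multimodal, so the global fit uses multi-start
trust-region least squares from log-spaced rate guesses (seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "BliTrace",
    "BindingFit",
    "TwoPhaseFit",
    "SteadyStateFit",
    "KdBound",
    "fit_one_phase_global",
    "fit_two_phase_decay",
    "equilibrium_response",
    "steady_state_kd",
    "kd_lower_bound",
]


@dataclass
class BliTrace:
    """One BLI phase: time (s, from phase start) and response (nm)."""

    t: np.ndarray
    response: np.ndarray
    phase: str  # "association" | "dissociation"
    analyte_conc: float  # uM
    loading: float = 1.0  # nm of immobilised ligand

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if len(self.t) != len(self.response):
            raise ValueError("t and response must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing within a phase")
        if self.phase not in ("association", "dissociation"):
            raise ValueError("phase must be 'association' or 'dissociation'")
        if self.loading <= 0:
            raise ValueError("loading must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Global one-phase kinetic fit results (rates in uM^-1 s^-1 / s^-1)."""

    kon: float
    koff: float
    bmax: float
    ses: tuple[float, float, float]
    rss: float

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.bmax <= 0:
            raise ValueError("rates and Bmax must be positive")


def _one_phase_model(params, traces):
    kon, koff, bmax = params
    resid = []
    for tr in traces:
        c = tr.analyte_conc
        req = bmax * c / (koff / kon + c)
        if tr.phase == "association":
            kobs = kon * c + koff
            model = req * (1.0 - np.exp(-kobs * tr.t))
        else:
            r0 = tr.response[0]
            model = r0 * np.exp(-koff * tr.t)
        resid.append(model - tr.response)
    return np.concatenate(resid)


def fit_one_phase_global(
    traces: Sequence[BliTrace],
    n_starts: int = 6,
    seed: int | None = 0,
) -> BindingFit:
    """Global one-phase fit with kon, koff, Bmax shared across all traces.

    Requires traces at >= 2 analyte concentrations with paired association
    and dissociation segments.  Multi-start trust-region least squares from
    log-spaced rate guesses; the best (lowest-RSS) converged start wins.
    """
    concs = sorted({tr.analyte_conc for tr in traces})
    if len(concs) < 2:
        raise ValueError("global fit needs >= 2 analyte concentrations")
    phases = {tr.phase for tr in traces}
    if phases != {"association", "dissociation"}:
        raise ValueError("need paired association and dissociation segments")
    rmax = max(tr.response.max() for tr in traces)
    rng = np.random.default_rng(seed)
    kon_grid = np.logspace(-2, 1, n_starts)
    koff_grid = np.logspace(-2.5, 0.5, n_starts)
    rng.shuffle(koff_grid)
    best = None
    for kon0, koff0 in zip(kon_grid, koff_grid):
        x0 = np.log([kon0, koff0, max(rmax, 1e-6)])

        def resid(logp):
            return _one_phase_model(np.exp(logp), traces)

        try:
            sol = least_squares(resid, x0, method="trf", max_nfev=2000)
        except Exception:
            continue
        rss = float(sol.cost * 2)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("one-phase global fit did not converge from any start")
    rss, sol = best
    params = np.exp(sol.x)
    # covariance of log-params from the Jacobian, delta method to natural scale
    J = sol.jac
    dof = max(len(sol.fun) - 3, 1)
    try:
        cov_log = np.linalg.inv(J.T @ J) * (rss / dof)
        ses = tuple(float(p * np.sqrt(max(cov_log[i, i], 0.0)))
                    for i, p in enumerate(params))
    except np.linalg.LinAlgError:
        ses = (np.nan, np.nan, np.nan)
    return BindingFit(kon=float(params[0]), koff=float(params[1]),
                      bmax=float(params[2]), ses=ses, rss=rss)


@dataclass(frozen=True)
class TwoPhaseFit:
    """Two-phase dissociation decay (plateau fixed at zero)."""

    a_fast: float
    k_fast: float
    a_slow: float
    k_slow: float
    collapsed_to_one_phase: bool
    rss: float

    @property
    def fast_fraction(self) -> float:
        return self.a_fast / (self.a_fast + self.a_slow) if not self.collapsed_to_one_phase else 1.0


def fit_two_phase_decay(
    trace: BliTrace,
    amplitude_ratio_floor: float = 1e-3,
    n_starts: int = 5,
) -> TwoPhaseFit:
    """Fit R(t) = A1 e^{-k1 t} + A2 e^{-k2 t} with zero final plateau.

    Components are labelled fast/slow by rate.  When the minor amplitude
    falls below ``amplitude_ratio_floor`` of the major one the fit collapses
    to a single exponential and is flagged.
    """
    if trace.phase != "dissociation":
        raise ValueError("two-phase decay applies to a dissociation segment")
    t = trace.t - trace.t[0]
    y = trace.response
    if len(t) < 10:
        raise ValueError("need >= 10 points")
    r0 = max(y[0], 1e-9)
    # crude rate scale from the overall decay
    span = t[-1] - t[0]
    k_scale = max(1.0 / span, 1e-6)
    best = None
    for ratio in np.logspace(0.5, 2.5, n_starts):

        def resid(p):
            a1, k1, a2, k2 = p
            return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) - y

        x0 = [0.5 * r0, k_scale * ratio, 0.5 * r0, k_scale / ratio]
        sol = least_squares(resid, x0, bounds=([0, 0, 0, 0], np.inf),
                            method="trf", max_nfev=2000)
        rss = float(sol.cost * 2)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    rss, p = best
    a1, k1, a2, k2 = p
    if k1 < k2:  # order fast first
        a1, k1, a2, k2 = a2, k2, a1, k1
    amp_min, amp_max = min(a1, a2), max(a1, a2)
    if amp_max <= 0 or amp_min / amp_max < amplitude_ratio_floor or np.isclose(k1, k2, rtol=1e-3):
        # refit single exponential
        def resid1(p):
            return p[0] * np.exp(-p[1] * t) - y

        sol1 = least_squares(resid1, [r0, k_scale], bounds=([0, 0], np.inf))
        a, k = sol1.x
        return TwoPhaseFit(a_fast=float(a), k_fast=float(k), a_slow=0.0,
                           k_slow=float(k), collapsed_to_one_phase=True,
                           rss=float(sol1.cost * 2))
    return TwoPhaseFit(a_fast=float(a1), k_fast=float(k1), a_slow=float(a2),
                       k_slow=float(k2), collapsed_to_one_phase=False, rss=rss)


def equilibrium_response(
    trace: BliTrace,
    window: tuple[float, float] = (45.0, 49.9),
    normalise_loading: bool = True,
) -> float:
    """Mean association response over a late time window, loading-normalised."""
    if trace.phase != "association":
        raise ValueError("equilibrium response comes from an association segment")
    lo, hi = window
    mask = (trace.t >= lo) & (trace.t <= hi)
    if not mask.any():
        raise ValueError(f"no points inside the averaging window {window}")
    r = float(trace.response[mask].mean())
    return r / trace.loading if normalise_loading else r


@dataclass(frozen=True)
class SteadyStateFit:
    kd: float
    bmax: float
    se_kd: float
    se_bmax: float
    ci95_kd: tuple[float, float] = (0.0, float("inf"))
    lower_bound_only: bool = False


def steady_state_kd(
    concs: Sequence[float],
    responses: Sequence[float],
    curvature_threshold: float = 0.1,
) -> SteadyStateFit:
    """One-site fit Req(C) = Bmax C / (KD + C) to equilibrium responses.

    With no measurable curvature over the tested range (responses consistent
    with a straight line through the origin, i.e. max C << KD) the result is
    flagged lower-bound-only and the fitted KD should be read as a bound.
    """
    c = np.asarray(concs, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) != len(r) or len(c) < 4:
        raise ValueError("need >= 4 (conc, response) pairs")

    def hyper(cc, bmax, kd):
        return bmax * cc / (kd + cc)

    p0 = [r.max() * 2, np.median(c)]
    popt, pcov = curve_fit(hyper, c, r, p0=p0, maxfev=20000,
                           bounds=([0, 0], np.inf))
    bmax, kd = popt
    se_bmax, se_kd = np.sqrt(np.clip(np.diag(pcov), 0, None))
    from scipy import stats as _st

    tcrit = float(_st.t.ppf(0.975, max(len(c) - 2, 1)))
    ci = (float(kd - tcrit * se_kd), float(kd + tcrit * se_kd))
    lower_only = bool(kd > c.max() / curvature_threshold)
    return SteadyStateFit(kd=float(kd), bmax=float(bmax), se_kd=float(se_kd),
                          se_bmax=float(se_bmax), ci95_kd=ci,
                          lower_bound_only=lower_only)


@dataclass(frozen=True)
class KdBound:
    kd_min: float
    c_max: float
    detect_fraction: float
    assumes_equal_bmax: bool = True


def kd_lower_bound(c_max: float, detect_fraction: float) -> KdBound:
    """KD lower bound from a no-binding observation at the top concentration.

    If binding is detectable down to ``detect_fraction * KD`` of analyte for
    a comparable interaction (equal Bmax assumed), then absence of signal at
    ``c_max`` implies KD > c_max / detect_fraction.
    """
    if not (0.0 < detect_fraction <= 1.0):
        raise ValueError("detect_fraction must be in (0, 1]")
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    return KdBound(kd_min=c_max / detect_fraction, c_max=c_max,
                   detect_fraction=detect_fraction)
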