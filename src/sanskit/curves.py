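"""Guinier, contrast-match-point and Stuhrmann analysis of 1-D SANS curves.

The three stages mirror the standard contrast-variation workflow:

1. Guinier fits of each reduced curve, ln I(q) = ln I(0) - (Rg^2/3) q^2,
   give the forward scattering I(0) and radius of gyration Rg per solvent
   contrast, with an automatic window search constrained by q*Rg bounds.
2. The signed scattering amplitudes sqrt(I(0)/c) plotted against the solvent
   D2O fraction fall on a line whose x-intercept is the contrast match point
   of the complex.
3. The Stuhrmann decomposition Rg^2 = Rm^2 + alpha/drho - beta/drho^2
   separates the infinite-contrast size (Rm), the radial distribution of
   scattering density (alpha) and the offset between the scattering-length
   density centre and the centre of mass (beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScatteringCurve",
    "GuinierResult",
    "CmpResult",
    "StuhrmannResult",
    "WindowRules",
    "GuinierError",
    "guinier_fit",
    "auto_guinier",
    "cmp_fit",
    "stuhrmann_fit",
    "stuhrmann_rg",
]


class GuinierError(ValueError):
    """Raised when a Guinier fit cannot be performed or violates its window rules."""


@dataclass
class ScatteringCurve:
    """One reduced 1-D SANS measurement with its solvent/labelling metadata."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    f_D2O: float = 0.0
    conc: float = 1.0  # mg/ml
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class WindowRules:
    """Configured q*Rg bounds for Guinier windows.

    Defaults reproduce the achieved experimental envelope
    0.15 <= qmin*Rg <= 0.57 and 0.39 <= qmax*Rg <= 1.3, with a documented
    exception tolerance allowing qmax*Rg up to 1.4.
    """

    qmin_rg: tuple[float, float] = (0.15, 0.57)
    qmax_rg: tuple[float, float] = (0.39, 1.3)
    qmax_rg_tolerance: float = 1.4


@dataclass(frozen=True)
class GuinierResult:
    I0: float
    Rg: float
    se_I0: float
    se_Rg: float
    q_range: tuple[float, float]
    n_points: int
    r2: float
    f_D2O: float = 0.0
    conc: float = 1.0
    n_dropped: int = 0

    @property
    def qmin_rg(self) -> float:
        return self.q_range[0] * self.Rg

    @property
    def qmax_rg(self) -> float:
        return self.q_range[1] * self.Rg


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, floor_scale: bool = False):
    """Weighted least squares on a design [1, x]; returns beta, cov, r2, rss.

    With ``floor_scale`` the covariance is never scaled below its nominal
    (weights-derived) value — guards against overfitting shrinkage when the
    weights are true measurement variances.
    """
    X = np.column_stack([np.ones_like(x), x])
    W = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    dof = len(x) - 2
    xtwx_inv = np.linalg.inv((X * w[:, None]).T @ X)
    scale = rss / dof if dof > 0 else 0.0
    if floor_scale:
        scale = max(scale, 1.0)
    cov = xtwx_inv * scale
    ybar = np.sum(w * y) / np.sum(w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return beta, cov, r2, rss


def guinier_fit(
    curve: ScatteringCurve,
    window: tuple[float, float],
    rules: WindowRules | None = None,
) -> GuinierResult:
    """Weighted Guinier fit over q in [qmin, qmax].

    ln I is regressed on q^2 with weights from the propagated relative errors
    (sigma_lnI = sigma/I).  Non-positive intensities inside the window are
    dropped with a count recorded; fewer than 5 usable points is an error.
    If ``rules`` is given, the achieved q*Rg values must satisfy them.
    """
    qmin, qmax = window
    if not qmin < qmax:
        raise GuinierError("window qmin must be < qmax")
    mask = (curve.q >= qmin) & (curve.q <= qmax)
    if mask.sum() < 5:
        raise GuinierError(f"only {int(mask.sum())} points in window, need >= 5")
    pos = curve.I > 0
    dropped = int((mask & ~pos).sum())
    mask &= pos
    if mask.sum() < 5:
        raise GuinierError("fewer than 5 positive-intensity points remain in window")
    q = curve.q[mask]
    I = curve.I[mask]
    sig = curve.sigma[mask]
    x = q**2
    y = np.log(I)
    w = (I / sig) ** 2
    beta, cov, r2, _ = _wls(x, y, w)
    if beta[1] >= 0:
        raise GuinierError("non-negative Guinier slope: no decaying Guinier region")
    Rg = float(np.sqrt(-3.0 * beta[1]))
    I0 = float(np.exp(beta[0]))
    se_slope = float(np.sqrt(max(cov[1, 1], 0.0)))
    se_Rg = 1.5 * se_slope / Rg if Rg > 0 else np.inf
    se_I0 = I0 * float(np.sqrt(max(cov[0, 0], 0.0)))
    res = GuinierResult(
        I0=I0, Rg=Rg, se_I0=se_I0, se_Rg=se_Rg,
        q_range=(float(q[0]), float(q[-1])), n_points=int(mask.sum()),
        r2=r2, f_D2O=curve.f_D2O, conc=curve.conc, n_dropped=dropped,
    )
    if rules is not None:
        lo, hi = rules.qmin_rg
        if not (lo <= res.qmin_rg <= hi):
            raise GuinierError(
                f"qmin*Rg = {res.qmin_rg:.3f} violates bound [{lo}, {hi}]"
            )
        lo2, hi2 = rules.qmax_rg
        if not (lo2 <= res.qmax_rg <= rules.qmax_rg_tolerance):
            raise GuinierError(
                f"qmax*Rg = {res.qmax_rg:.3f} violates bound [{lo2}, {hi2}] "
                f"(tolerance {rules.qmax_rg_tolerance})"
            )
    return res


def auto_guinier(
    curve: ScatteringCurve,
    rules: WindowRules | None = None,
    max_iter: int = 100,
) -> GuinierResult:
    """Automatic Guinier window selection by self-consistent q*Rg bounds.

    For each candidate low-q start index a fixed-point iteration on Rg
    chooses the largest upper index with qmax*Rg <= bound; windows whose
    converged fit satisfies the configured qmin*Rg and qmax*Rg rules are
    collected.  Among near-best fits (weighted r^2 within 0.01 of the best)
    the window with the most points wins, ties broken by smaller qmin.
    Raises :class:`GuinierError` naming the best attempt when no
    self-consistent window exists.
    """
    rules = rules or WindowRules()
    q = curve.q
    n = len(q)
    if n < 10:
        raise GuinierError("too few points for automatic window selection")

    def converge_end(i0: int) -> GuinierResult | None:
        """Fixed-point iterate the window end for a fixed start index."""
        try:
            res = guinier_fit(curve, (q[i0], q[min(i0 + 9, n - 1)]))
        except GuinierError:
            return None
        prev_i1 = -1
        for _ in range(max_iter):
            i1 = int(np.searchsorted(q, rules.qmax_rg[1] / res.Rg, side="right")) - 1
            i1 = min(max(i1, i0 + 4), n - 1)
            if i1 == prev_i1:
                return res
            prev_i1 = i1
            try:
                res = guinier_fit(curve, (q[i0], q[i1]))
            except GuinierError:
                return None
        return res

    # baseline: double fixed point, letting the start rise until qmin*Rg
    # clears its lower bound under the current Rg estimate
    i0 = 0
    seen: set[int] = set()
    base = None
    while i0 not in seen:
        seen.add(i0)
        res = converge_end(i0)
        if res is None:
            break
        base = res
        i0_new = int(np.searchsorted(q, rules.qmin_rg[0] / res.Rg))
        i0_new = min(max(i0_new, 0), n - 6)
        if i0_new == i0:
            break
        i0 = i0_new
    i0_base = i0 if base is not None else 0

    candidates: list[GuinierResult] = []
    best_attempt: str | None = None
    for off in range(-2, 13):  # local scan around the baseline start
        j0 = i0_base + off
        if not (0 <= j0 <= n - 6):
            continue
        res = converge_end(j0)
        if res is None:
            continue
        lo, hi = rules.qmin_rg
        lo2 = rules.qmax_rg[0]
        if lo <= res.qmin_rg <= hi and lo2 <= res.qmax_rg <= rules.qmax_rg[1]:
            candidates.append(res)
        else:
            best_attempt = (
                f"window ({res.q_range[0]:.4g}, {res.q_range[1]:.4g}) converged to "
                f"qmin*Rg={res.qmin_rg:.3f}, qmax*Rg={res.qmax_rg:.3f} outside rules"
            )
    if not candidates:
        raise GuinierError(
            "no self-consistent Guinier window; best attempt: "
            + (best_attempt or "no fittable window")
        )
    best_r2 = max(c.r2 for c in candidates)
    good = [c for c in candidates if c.r2 >= best_r2 - 0.01]
    good.sort(key=lambda c: (-c.n_points, c.q_range[0]))
    return good[0]


@dataclass(frozen=True)
class CmpResult:
    """Contrast match point from a signed scattering-amplitude line."""

    cmp: float
    ci95: tuple[float, float]
    slope: float
    intercept: float
    signs: tuple[int, ...]
    extrapolated: bool

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.cmp <= self.ci95[1]):
            raise ValueError("confidence interval must contain the match point")


def cmp_fit(series: Sequence[GuinierResult]) -> CmpResult:
    """Match point from the x-intercept of signed sqrt(I0/c) vs f_D2O.

    Of the two possible sign assignments along the sorted D2O axis (all
    combinations of one sign change), the one minimising the residual sum of
    squares is used.  The 95% CI comes from t-propagation of the weighted-fit
    covariance through cmp = -intercept/slope.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 contrasts for a match-point fit")
    order = np.argsort([g.f_D2O for g in series])
    gs = [series[i] for i in order]
    f = np.array([g.f_D2O for g in gs])
    if len(np.unique(f)) < 3:
        raise ValueError("need at least 3 distinct D2O fractions")
    amp = np.array([np.sqrt(g.I0 / g.conc) for g in gs])
    # se of sqrt(I0/c) by delta method
    se = np.array([
        g.se_I0 / (2.0 * np.sqrt(g.I0 * g.conc)) if g.se_I0 > 0 else 0.0
        for g in gs
    ])
    w = 1.0 / se**2 if np.all(se > 0) else np.ones_like(amp)
    n = len(f)
    best = None
    for k in range(n + 1):  # sign flips after index k-1
        signs = np.where(np.arange(n) < k, 1.0, -1.0)
        y = signs * amp
        # floor the covariance scale at nominal: the sign-split selection can
        # otherwise overfit and shrink the CI below the measurement errors
        beta, cov, r2, rss = _wls(f, y, w, floor_scale=np.all(se > 0))
        if best is None or rss < best[0]:
            best = (rss, beta, cov, signs)
    _, beta, cov, signs = best
    b0, b1 = beta
    if abs(b1) < 1e-300:
        raise ValueError("zero slope: no match point")
    cmp_val = -b0 / b1
    # delta-method variance of -b0/b1
    var = (cov[0, 0] + cmp_val**2 * cov[1, 1] + 2 * cmp_val * cov[0, 1]) / b1**2
    tcrit = stats.t.ppf(0.975, max(n - 2, 1))
    half = tcrit * np.sqrt(max(var, 0.0))
    extrapolated = not (f.min() <= cmp_val <= f.max())
    return CmpResult(
        cmp=float(cmp_val),
        ci95=(float(cmp_val - half), float(cmp_val + half)),
        slope=float(b1),
        intercept=float(b0),
        signs=tuple(int(s) for s in signs),
        extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class StuhrmannResult:
    """Rg^2 = Rm^2 + alpha/drho - beta/drho^2 decomposition."""

    Rm2: float
    alpha: float
    beta: float
    se_Rm2: float
    se_alpha: float
    se_beta: float
    model: str  # "linear" or "quadratic"
    r2_linear: float
    r2_quadratic: float

    def __post_init__(self) -> None:
        if self.model not in ("linear", "quadratic"):
            raise ValueError("model must be 'linear' or 'quadratic'")
        if self.model == "linear" and self.beta != 0.0:
            raise ValueError("linear model must have beta = 0")


def _ols_design(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    W = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    dof = len(y) - X.shape[1]
    cov = np.linalg.inv((X * w[:, None]).T @ X) * (rss / dof if dof > 0 else 0.0)
    ybar = np.sum(w * y) / np.sum(w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return beta, cov, r2


def stuhrmann_fit(
    rg: Sequence[float],
    delta_rho: Sequence[float],
    se_rg: Sequence[float] | None = None,
    linear_margin: float = 0.02,
) -> StuhrmannResult:
    """Fit the Stuhrmann relation to (Rg, contrast) pairs.

    Both the linear (beta = 0) and the full quadratic model in x = 1/drho are
    fitted; the quadratic always has r^2 >= linear (nested models).  The
    linear model is selected when its r^2 is within ``linear_margin`` of the
    quadratic's, mirroring the usual preference for the simpler model when
    the data do not support a resolvable SLD-centre offset.
    """
    rg = np.asarray(rg, dtype=float)
    drho = np.asarray(delta_rho, dtype=float)
    if len(rg) != len(drho):
        raise ValueError("rg and delta_rho length mismatch")
    if np.any(drho == 0):
        raise ValueError("zero contrast point: 1/drho undefined")
    x = 1.0 / drho
    if len(np.unique(np.round(x, 12))) < 3:
        raise ValueError("need >= 3 distinct 1/drho values")
    if len(rg) < 3:
        raise ValueError("need >= 3 points for the linear Stuhrmann fit")
    y = rg**2
    if se_rg is not None:
        se_y = 2.0 * rg * np.asarray(se_rg, dtype=float)
        w = np.where(se_y > 0, 1.0 / np.maximum(se_y, 1e-30) ** 2, 1.0)
    else:
        w = np.ones_like(y)
    Xlin = np.column_stack([np.ones_like(x), x])
    beta_l, cov_l, r2_l = _ols_design(Xlin, y, w)
    can_quad = len(rg) >= 4
    if can_quad:
        Xq = np.column_stack([np.ones_like(x), x, -(x**2)])
        beta_q, cov_q, r2_q = _ols_design(Xq, y, w)
    else:
        beta_q, cov_q, r2_q = beta_l, cov_l, r2_l
    use_linear = (not can_quad) or (r2_q - r2_l < linear_margin)
    if use_linear:
        return StuhrmannResult(
            Rm2=float(beta_l[0]), alpha=float(beta_l[1]), beta=0.0,
            se_Rm2=float(np.sqrt(max(cov_l[0, 0], 0))),
            se_alpha=float(np.sqrt(max(cov_l[1, 1], 0))),
            se_beta=0.0, model="linear",
            r2_linear=r2_l, r2_quadratic=r2_q,
        )
    return StuhrmannResult(
        Rm2=float(beta_q[0]), alpha=float(beta_q[1]), beta=float(beta_q[2]),
        se_Rm2=float(np.sqrt(max(cov_q[0, 0], 0))),
        se_alpha=float(np.sqrt(max(cov_q[1, 1], 0))),
        se_beta=float(np.sqrt(max(cov_q[2, 2], 0))),
        model="quadratic", r2_linear=r2_l, r2_quadratic=r2_q,
    )


def stuhrmann_rg(result: StuhrmannResult, delta_rho: float) -> float:
    """Model Rg at a given contrast; errors when the radicand is negative."""
    rg2 = result.Rm2 + result.alpha / delta_rho - result.beta / delta_rho**2
    if rg2 < 0:
        raise ValueError(
            f"negative Rg^2 = {rg2:.4g} at drho = {delta_rho:.4g}: "
            "contrast too close to the match point"
        )
    return float(np.sqrt(rg2))
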