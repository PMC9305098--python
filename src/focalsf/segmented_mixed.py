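"""Broken-stick regression on a random-intercept mixed model.

Pools the focal records of all VF locations and fits a segmented
(two-slope) relationship between a focal structural value and fVFD with a
per-subject random intercept.  The default orientation regresses the
structural value on fVFD, so the breakpoint sits directly on the dB axis
and slopes are in structure-per-dB; the opposite orientation is available.
The breakpoint is estimated by iterative linearization (reparameterize
around the current breakpoint, fit, shift by the ratio of the gap and
slope-change coefficients), and the existence of a slope change is tested
with a Davies-type supremum test over a candidate grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_random_intercept, whiten

__all__ = [
    "SegmentedFitResult",
    "fit_segmented_lmm",
    "davies_test",
    "breakpoint_report",
]

PREDICTOR_COLUMNS = {"fCD": "fCD", "fRNFLT": "fRNFLT_um"}

#: Regression orientations.  ``struct_on_fvfd`` regresses the structural
#: value on fVFD with the breakpoint on the fVFD (dB) axis, which is the
#: orientation that makes the reported slope units (structure per dB) and
#: "fVFD at breakpoint" immediate.  ``fvfd_on_struct`` regresses fVFD on
#: the structural predictor and maps the breakpoint onto the response
#: scale through the fitted line.
ORIENTATIONS = ("struct_on_fvfd", "fvfd_on_struct")


@dataclass(frozen=True)
class SegmentedFitResult:
    """Breakpoint fit for one structural predictor.

    ``psi`` lives on the regressor axis of the chosen orientation; under
    the default (structure on fVFD) it is already in dB and equals
    ``fvfd_at_bp``.  Under the opposite orientation ``fvfd_at_bp`` is the
    breakpoint's image on the response scale through the fitted line.
    """

    predictor_id: str
    psi: float
    slope_before: float
    slope_change: float
    fvfd_at_bp: float
    ci_psi: tuple[float, float]
    ci_slope_before: tuple[float, float]
    ci_slope_change: tuple[float, float]
    ci_fvfd_at_bp: tuple[float, float]
    sigma_b: float
    sigma_e: float
    converged: bool
    n_iter: int
    n: int
    n_subjects: int
    davies_p: float | None = None
    history: tuple[float, ...] = field(default_factory=tuple)


def _extract(records: pd.DataFrame, predictor_id: str, orientation: str):
    if predictor_id not in PREDICTOR_COLUMNS:
        raise ValueError(f"unknown predictor {predictor_id!r}")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    col = PREDICTOR_COLUMNS[predictor_id]
    if col not in records.columns and predictor_id in records.columns:
        col = predictor_id
    vcol = "fVFD_db" if "fVFD_db" in records.columns else "fVFD"
    df = records.dropna(subset=[col, vcol])
    struct = df[col].to_numpy(float)
    fvfd = df[vcol].to_numpy(float)
    g = df["subject_id"].to_numpy()
    if orientation == "struct_on_fvfd":
        return struct, fvfd, g
    return fvfd, struct, g


def _segmented_design(x: np.ndarray, psi: float, with_gap: bool) -> np.ndarray:
    above = x > psi
    U = (x - psi) * above
    cols = [np.ones_like(x), x, U]
    if with_gap:
        cols.append(-above.astype(float))
    return np.column_stack(cols)


def fit_segmented_lmm(
    records: pd.DataFrame,
    predictor_id: str,
    psi_init: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
    reml: bool = True,
    with_davies: bool = False,
    orientation: str = "struct_on_fvfd",
) -> SegmentedFitResult:
    """Muggeo-style iterative linearization on the random-intercept model.

    At the current breakpoint psi the working model is
    y ~ 1 + x + U + V (+ random intercept per subject) with
    U = (x-psi)*1[x>psi] and V = -1[x>psi]; psi moves by coef(V)/coef(U)
    with step-halving so the likelihood never decreases, and convergence is
    declared when the update falls below ``tol`` of the regressor range.
    The default orientation puts the structural value on the response side
    and fVFD on the regressor side, so psi is directly in dB.
    """
    y, x, g = _extract(records, predictor_id, orientation)
    n_subjects = np.unique(g).size
    if n_subjects < 2 or np.unique(x).size < 4:
        raise ValueError("need >= 2 subjects and spread in the predictor")
    x_lo, x_hi = float(x.min()), float(x.max())
    x_range = x_hi - x_lo
    psi = float(np.median(x)) if psi_init is None else float(psi_init)
    if not (x_lo < psi < x_hi):
        raise ValueError("psi_init outside the predictor support")
    if not ((x < psi).sum() >= 2 and (x > psi).sum() >= 2):
        raise ValueError("predictor has no spread on both sides of psi_init")

    history = [psi]
    converged = False
    fit = fit_random_intercept(y, _segmented_design(x, psi, True), g, reml=reml)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gamma, beta_u = fit.beta[3], fit.beta[2]
        if beta_u == 0:
            break
        delta = gamma / beta_u
        # cap the raw update (a tiny slope-change coefficient can make it
        # astronomically large), then halve until the candidate stays in the
        # support and does not degrade the likelihood
        step = float(np.clip(delta, -x_range, x_range))
        best = None
        for _ in range(30):
            cand = psi + step
            # valid candidates keep at least two observations on each side,
            # otherwise the gap and slope-change columns become collinear
            if x_lo < cand < x_hi and (x > cand).sum() >= 2 and (x < cand).sum() >= 2:
                try:
                    cand_fit = fit_random_intercept(
                        y, _segmented_design(x, cand, True), g, reml=reml
                    )
                except ValueError:
                    cand_fit = None
                if cand_fit is not None and cand_fit.loglik >= fit.loglik - 1e-9:
                    best = (cand, cand_fit)
                    break
            step /= 2.0
        if best is None:
            # no admissible move improves the likelihood: the iterate sits on
            # a kink of the piecewise profile, which is convergence
            converged = True
            break
        new_psi, new_fit = best
        moved = abs(new_psi - psi)
        psi, fit = new_psi, new_fit
        history.append(psi)
        if moved < tol * x_range:
            converged = True
            break

    # local polish: the linearization stalls at kinks of the piecewise
    # profile likelihood, so finish with a bounded 1-D search of the ML
    # profile around the final iterate
    psi = _polish_psi(y, x, g, psi, x_lo, x_hi)
    fit = fit_random_intercept(y, _segmented_design(x, psi, True), g, reml=reml)

    z = stats.norm.ppf(0.975)
    ci_psi = _profile_ci_psi(y, x, g, psi, x_lo, x_hi)

    # clean fit at the final breakpoint (gap term dropped) for reporting
    final = fit_random_intercept(y, _segmented_design(x, psi, False), g, reml=reml)
    b0, b1, bu = final.beta
    c = final.cov_beta

    # slope CIs: envelope of Wald intervals over the breakpoint's profile
    # interval, so breakpoint uncertainty propagates into the slopes (a
    # plain Wald CI at the selected psi undercovers when the break is weak)
    slope_cis = []
    for p_eval in {psi, *ci_psi}:
        p_eval = min(max(p_eval, x_lo + 1e-9), x_hi - 1e-9)
        try:
            f = fit_random_intercept(
                y, _segmented_design(x, p_eval, False), g, reml=reml
            )
        except ValueError:
            continue
        se1 = math.sqrt(f.cov_beta[1, 1])
        se2 = math.sqrt(f.cov_beta[2, 2])
        slope_cis.append(
            (
                (f.beta[1] - z * se1, f.beta[1] + z * se1),
                (f.beta[2] - z * se2, f.beta[2] + z * se2),
            )
        )
    if orientation == "struct_on_fvfd":
        # the regressor *is* fVFD, so the breakpoint is already in dB
        fvfd_at_bp = psi
        ci_fvfd = ci_psi
    else:
        fvfd_at_bp = b0 + b1 * psi
        se_bp_resp = math.sqrt(
            max(c[0, 0] + psi**2 * c[1, 1] + 2 * psi * c[0, 1], 0.0)
        )
        ci_fvfd = (fvfd_at_bp - z * se_bp_resp, fvfd_at_bp + z * se_bp_resp)
    ci_b1 = (
        min(ci[0][0] for ci in slope_cis),
        max(ci[0][1] for ci in slope_cis),
    )
    ci_bu = (
        min(ci[1][0] for ci in slope_cis),
        max(ci[1][1] for ci in slope_cis),
    )

    davies_p = None
    if with_davies:
        davies_p = davies_test(records, predictor_id, orientation=orientation)

    return SegmentedFitResult(
        predictor_id=predictor_id,
        psi=psi,
        slope_before=b1,
        slope_change=bu,
        fvfd_at_bp=fvfd_at_bp,
        ci_psi=ci_psi,
        ci_slope_before=ci_b1,
        ci_slope_change=ci_bu,
        ci_fvfd_at_bp=ci_fvfd,
        sigma_b=final.sigma_b,
        sigma_e=final.sigma_e,
        converged=converged,
        n_iter=n_iter,
        n=final.n,
        n_subjects=n_subjects,
        davies_p=davies_p,
        history=tuple(history),
    )


def _polish_psi(
    y: np.ndarray,
    x: np.ndarray,
    g: np.ndarray,
    psi: float,
    x_lo: float,
    x_hi: float,
    window_frac: float = 0.05,
) -> float:
    from scipy.optimize import minimize_scalar

    w = window_frac * (x_hi - x_lo)
    # keep at least two observations on each side of every candidate
    xs = np.sort(np.unique(x))
    lo = max(xs[2] + 1e-12, psi - w)
    hi = min(xs[-3] - 1e-12, psi + w)
    if not lo < hi:
        return psi

    def neg_ll(p: float) -> float:
        try:
            return -fit_random_intercept(
                y, _segmented_design(x, p, False), g, reml=False
            ).loglik
        except ValueError:
            return np.inf

    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6 * (x_hi - x_lo)})
    return float(res.x) if res.fun <= neg_ll(psi) else psi


def _profile_ci_psi(
    y: np.ndarray,
    x: np.ndarray,
    g: np.ndarray,
    psi_hat: float,
    x_lo: float,
    x_hi: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood interval for the breakpoint.

    Inverts the ML likelihood-ratio statistic over the breakpoint axis:
    the interval is {psi : 2*(ll(psi_hat) - ll(psi)) < chi2_1(level)}.
    Delta-method Wald intervals undercover noticeably here because the
    likelihood in psi is asymmetric; the profile interval does not.
    """
    crit = stats.chi2.ppf(level, 1)

    def ll(psi: float) -> float:
        try:
            return fit_random_intercept(
                y, _segmented_design(x, psi, False), g, reml=False
            ).loglik
        except ValueError:  # no support beyond psi: treat as infinitely bad
            return -np.inf

    ll_hat = ll(psi_hat)

    def bound(direction: float) -> float:
        limit = x_hi if direction > 0 else x_lo
        step = (limit - psi_hat) * 0.98
        inner, outer = psi_hat, psi_hat + step
        if 2.0 * (ll_hat - ll(outer)) < crit:
            return outer  # CI runs to the edge of the support
        for _ in range(60):
            mid = 0.5 * (inner + outer)
            if 2.0 * (ll_hat - ll(mid)) < crit:
                inner = mid
            else:
                outer = mid
            if abs(outer - inner) < 1e-5 * (x_hi - x_lo):
                break
        return 0.5 * (inner + outer)

    return (bound(-1.0), bound(+1.0))


def davies_test(
    records: pd.DataFrame,
    predictor_id: str,
    k_grid: int = 10,
    quantiles: tuple[float, float] = (0.05, 0.95),
    orientation: str = "struct_on_fvfd",
) -> float:
    """Davies-type test for the existence of a slope change.

    Fits the linear null (no break) mixed model, whitens by the estimated
    covariance, computes the Wald statistic of the slope-change term at
    ``k_grid`` candidate breakpoints between the stated predictor
    quantiles, and combines them through Davies' upper bound for the
    supremum of a Gaussian process over the grid.
    """
    if k_grid < 5:
        raise ValueError("k_grid must be >= 5")
    y, x, g = _extract(records, predictor_id, orientation)
    null_design = np.column_stack([np.ones_like(x), x])
    null_fit = fit_random_intercept(y, null_design, g, reml=True)
    yw_base, _ = whiten(y, null_design, g, null_fit.lam)

    lo, hi = np.quantile(x, quantiles)
    candidates = np.linspace(lo, hi, k_grid)
    zs = []
    for psi in candidates:
        X = _segmented_design(x, psi, False)
        yw, Xw = whiten(y, X, g, null_fit.lam)
        XtX = Xw.T @ Xw
        if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
            continue
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        dof = max(yw.size - Xw.shape[1], 1)
        s2 = float(resid @ resid) / dof
        var_bu = s2 * np.linalg.inv(XtX)[2, 2]
        zs.append(beta[2] / math.sqrt(var_bu))
    if len(zs) < 2:
        raise ValueError("all candidate breakpoints collinear")
    zs = np.array(zs)
    m = float(np.abs(zs).max())
    total_variation = float(np.abs(np.diff(zs)).sum())
    p = 2.0 * (
        stats.norm.sf(m)
        + total_variation * math.exp(-0.5 * m * m) / math.sqrt(8.0 * math.pi)
    )
    return float(min(1.0, max(p, np.finfo(float).tiny)))


def breakpoint_report(results: dict[str, SegmentedFitResult]) -> pd.DataFrame:
    """Slope-before / fVFD-at-breakpoint / slope-change table with 95% CIs."""
    rows = []
    for pid, res in results.items():
        for name, point, ci in [
            ("slope_before", res.slope_before, res.ci_slope_before),
            ("fvfd_at_bp", res.fvfd_at_bp, res.ci_fvfd_at_bp),
            ("slope_change", res.slope_change, res.ci_slope_change),
        ]:
            if not (min(ci) <= point <= max(ci)):
                raise AssertionError(f"{pid}/{name}: CI does not contain the estimate")
        rows.append(
            {
                "predictor": pid,
                "slope_before": res.slope_before,
                "slope_before_ci": list(res.ci_slope_before),
                "fvfd_at_bp": res.fvfd_at_bp,
                "fvfd_at_bp_ci": list(res.ci_fvfd_at_bp),
                "slope_change": res.slope_change,
                "slope_change_ci": list(res.ci_slope_change),
                "davies_p": res.davies_p,
                "converged": res.converged,
                "note": "" if res.converged else "DID NOT CONVERGE",
            }
        )
    return pd.DataFrame(rows)
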