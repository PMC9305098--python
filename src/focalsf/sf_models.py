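"""Per-location and global structure-function regression models.

Three nested ordinary-least-squares models of focal visual-field deviation:

    Mv : fVFD = b0 + b1*fCD
    Mt : fVFD = b0 + b1*fRNFL-T
    Mvt: fVFD = b0 + b1*fCD + b2*fRNFL-T + b3*fCD*fRNFL-T

compared per VF location by Pearson correlation of fitted vs. observed
values, AIC (full Gaussian likelihood, error variance counted as a
parameter), and likelihood-ratio tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MODEL_IDS",
    "ModelFitResult",
    "ComparisonResult",
    "fit_location",
    "fit_all_locations",
    "compare_models",
    "location_maps",
    "plot_field_map",
    "global_fit",
]

MODEL_IDS = ("Mv", "Mt", "Mvt")

_MODEL_TERMS = {
    "Mv": ("fCD",),
    "Mt": ("fRNFLT",),
    "Mvt": ("fCD", "fRNFLT", "fCD:fRNFLT"),
}

MIN_RECORDS = 10


@dataclass(frozen=True)
class ModelFitResult:
    location_index: int
    model_id: str
    coefficients: tuple[float, ...]
    rss: float
    loglik: float
    aic: float
    r_p: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    location_index: int
    pair: str
    delta_aic: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    winner_by_aic: str
    lrt_significant: bool


def _design(df: pd.DataFrame, model_id: str) -> np.ndarray:
    cols = []
    for term in _MODEL_TERMS[model_id]:
        if ":" in term:
            a, b = term.split(":")
            cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            cols.append(df[term].to_numpy(float))
    X = np.column_stack(cols)
    return sm.add_constant(X, has_constant="add")


def _gaussian_loglik(rss: float, n: int) -> float:
    # profile log-likelihood at the MLE sigma^2 = rss/n, constants included
    if rss <= 0:
        rss = np.finfo(float).tiny
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


def fit_location(
    records: pd.DataFrame,
    model_id: str,
    location_index: int | None = None,
    min_records: int = MIN_RECORDS,
) -> ModelFitResult:
    """OLS fit of one model equation on one location's records.

    ``records`` needs columns ``fVFD``, ``fCD``, ``fRNFLT``.  The reported
    AIC is -2*loglik + 2*(k+1), counting the error variance as a parameter;
    ``r_p`` is the Pearson correlation between fitted and observed fVFD.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if location_index is None:
        location_index = int(records["loc_index"].iloc[0]) if "loc_index" in records else -1
    n = len(records)
    if n < min_records:
        raise ValueError(
            f"location {location_index}: {n} records < required {min_records}"
        )
    y = records["fVFD"].to_numpy(float)
    X = _design(records, model_id)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"location {location_index}: collinear or constant predictors for {model_id}"
        )
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    ll = _gaussian_loglik(rss, n)
    k = X.shape[1]
    fitted = np.asarray(fit.fittedvalues)
    if np.std(fitted) == 0 or np.std(y) == 0:
        r_p = 0.0
    else:
        r_p = float(np.corrcoef(fitted, y)[0, 1])
    return ModelFitResult(
        location_index=location_index,
        model_id=model_id,
        coefficients=tuple(float(b) for b in fit.params),
        rss=rss,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * (k + 1),
        r_p=r_p,
        p_value=float(fit.f_pvalue),
        n=n,
    )


def compare_models(full: ModelFitResult, reduced: ModelFitResult, alpha: float = 0.05) -> ComparisonResult:
    """AIC difference and likelihood-ratio test of nested fits on identical records."""
    if full.n != reduced.n:
        raise ValueError(f"differing n: {full.n} vs {reduced.n}")
    if full.location_index != reduced.location_index:
        raise ValueError("fits are for different locations")
    df = len(full.coefficients) - len(reduced.coefficients)
    if df <= 0:
        raise ValueError("reduced model is not nested in full model")
    lrt_stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return ComparisonResult(
        location_index=full.location_index,
        pair=f"{full.model_id}_vs_{reduced.model_id}",
        delta_aic=full.aic - reduced.aic,
        lrt_stat=lrt_stat,
        lrt_df=df,
        lrt_p=float(stats.chi2.sf(lrt_stat, df)),
        winner_by_aic=full.model_id if full.aic < reduced.aic else reduced.model_id,
        lrt_significant=bool(stats.chi2.sf(lrt_stat, df) < alpha),
    )


def fit_all_locations(
    table: pd.DataFrame,
    min_records: int = MIN_RECORDS,
) -> tuple[dict[int, dict[str, ModelFitResult]], dict[int, dict[str, ComparisonResult]]]:
    """Fit Mv, Mt, Mvt at every location of an analysis table.

    The table uses the focal_metrics dialect (``subject_id``, ``loc_index``,
    ``fVFD_db``, ``fCD``, ``fRNFLT_um``); listwise deletion of incomplete
    rows is applied per location.
    """
    df = table.rename(
        columns={"fVFD_db": "fVFD", "fRNFLT_um": "fRNFLT"}
    ).dropna(subset=["fVFD", "fCD", "fRNFLT"])
    fits: dict[int, dict[str, ModelFitResult]] = {}
    comps: dict[int, dict[str, ComparisonResult]] = {}
    for loc_index, group in df.groupby("loc_index"):
        loc_fits = {
            mid: fit_location(group, mid, int(loc_index), min_records)
            for mid in MODEL_IDS
        }
        fits[int(loc_index)] = loc_fits
        comps[int(loc_index)] = {
            "Mvt_vs_Mv": compare_models(loc_fits["Mvt"], loc_fits["Mv"]),
            "Mvt_vs_Mt": compare_models(loc_fits["Mvt"], loc_fits["Mt"]),
        }
    return fits, comps


def location_maps(
    fits: dict[int, dict[str, ModelFitResult]],
    comps: dict[int, dict[str, ComparisonResult]],
    alphas: tuple[float, ...] = (0.05, 0.001),
) -> dict:
    """Per-location significance/winner tables plus r_p summaries."""
    sig_rows = []
    for loc, by_model in sorted(fits.items()):
        row = {"loc_index": loc}
        for mid, fit in by_model.items():
            row[f"r_p_{mid}"] = fit.r_p
            row[f"p_{mid}"] = fit.p_value
            for a in alphas:
                row[f"sig_{mid}_at_{a:g}"] = fit.p_value < a
        sig_rows.append(row)
    comp_rows = []
    for loc, by_pair in sorted(comps.items()):
        for pair, comp in by_pair.items():
            comp_rows.append(
                {
                    "loc_index": loc,
                    "pair": pair,
                    "delta_aic": comp.delta_aic,
                    "aic_favors_full": comp.delta_aic < 0,
                    "lrt_stat": comp.lrt_stat,
                    "lrt_p": comp.lrt_p,
                    "lrt_significant": comp.lrt_significant,
                }
            )
    sig_table = pd.DataFrame(sig_rows)
    comp_table = pd.DataFrame(comp_rows)
    summary = {
        "n_locations": len(fits),
        "r_p_mean": {
            mid: float(np.mean([f[mid].r_p for f in fits.values()])) for mid in MODEL_IDS
        },
        "r_p_sd": {
            mid: float(np.std([f[mid].r_p for f in fits.values()], ddof=1))
            for mid in MODEL_IDS
        },
        "aic_wins_full": {
            pair: int(
                sum(c[pair].delta_aic < 0 for c in comps.values())
            )
            for pair in ("Mvt_vs_Mv", "Mvt_vs_Mt")
        },
        "lrt_wins_full": {
            pair: int(sum(c[pair].lrt_significant for c in comps.values()))
            for pair in ("Mvt_vs_Mv", "Mvt_vs_Mt")
        },
        "n_significant": {
            f"{mid}_at_{a:g}": int(
                sum(f[mid].p_value < a for f in fits.values())
            )
            for mid in MODEL_IDS
            for a in alphas
        },
    }
    return {"significance": sig_table, "comparisons": comp_table, "summary": summary}


def plot_field_map(
    values_by_location: dict[int, bool | float],
    grid,
    path,
    title: str = "",
) -> None:
    """Render a per-location map in field coordinates (degrees).

    Boolean values plot green/red (significant / not significant); numeric
    values use a diverging colormap.  ``grid`` is the VF location list.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_index = {loc.index: loc for loc in grid}
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    vals = values_by_location
    numeric = not all(isinstance(v, (bool, np.bool_)) for v in vals.values())
    if numeric:
        xs = [by_index[i].x_deg for i in vals]
        ys = [by_index[i].y_deg for i in vals]
        sc = ax.scatter(xs, ys, c=list(vals.values()), cmap="RdYlGn", s=90)
        fig.colorbar(sc, ax=ax, shrink=0.8)
    else:
        for i, v in vals.items():
            loc = by_index[i]
            ax.scatter(loc.x_deg, loc.y_deg, c="green" if v else "red", s=90)
    for loc in grid:
        if loc.is_blind_spot:
            ax.scatter(loc.x_deg, loc.y_deg, c="black", s=90)
    ax.set_xlim(-30, 30)
    ax.set_ylim(-30, 30)
    ax.set_xlabel("eccentricity (deg)")
    ax.set_ylabel("eccentricity (deg)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def global_fit(per_subject: pd.DataFrame) -> dict[str, ModelFitResult]:
    """Cohort-level fits of the three equations with MD as the response.

    ``per_subject`` needs columns ``md_db``, ``global_cd``, ``global_rnflt_um``.
    """
    df = pd.DataFrame(
        {
            "fVFD": per_subject["md_db"].to_numpy(float),
            "fCD": per_subject["global_cd"].to_numpy(float),
            "fRNFLT": per_subject["global_rnflt_um"].to_numpy(float),
        }
    )
    return {mid: fit_location(df, mid, location_index=0) for mid in MODEL_IDS}
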