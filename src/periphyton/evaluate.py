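"""Metric performance against the stressor and the geographic gradient.

Every metric is regressed on log₂(mat P) (ordinary least squares) and scored
by adjusted R²; a second model regresses each metric (or mat P itself) on
latitude, longitude and their interaction as a surrogate for distance from
the disturbance source. Metric families (type, source, trait) are compared
with one-way ANOVA + Tukey HSD on the adjusted R² values and with
Kruskal–Wallis tests on within-group ranks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "fit_metric_gradient",
    "latlong_model",
    "performance_table",
    "family_anova",
    "grouped_ranks",
    "family_kruskal",
]

RANK_SCHEMES = {
    # factor ranked within groups of the remaining two factors
    "type": ("source", "trait"),
    "source": ("type", "trait"),
    "trait": ("type", "source"),
}


def fit_metric_gradient(values, mat_p) -> tuple[float, float, float]:
    """OLS of a metric on log₂(mat P): ``(slope, adjusted R², p)``.

    Requires ≥ 4 complete pairs. A constant metric is flagged by slope 0 and
    non-positive adjusted R².
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(mat_p, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 4:
        raise ValueError(f"need >= 4 paired observations, got {ok.sum()}")
    y, x = y[ok], np.log2(x[ok])
    if np.ptp(y) == 0:
        return 0.0, 0.0, 1.0
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.rsquared_adj), float(model.pvalues[1])


def latlong_model(values, latitude, longitude) -> float:
    """Adjusted R² of ``values ~ lat + long + lat·long`` (NaN if degenerate)."""
    y = np.asarray(values, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    ok = np.isfinite(y) & np.isfinite(lat) & np.isfinite(lon)
    if ok.sum() < 6:
        raise ValueError(f"need >= 6 complete cases, got {ok.sum()}")
    X = sm.add_constant(
        np.column_stack([lat[ok], lon[ok], lat[ok] * lon[ok]])
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear lat/long design; adjusted R² undefined")
        return np.nan
    return float(sm.OLS(y[ok], X).fit().rsquared_adj)


def performance_table(
    metric_values: pd.DataFrame,
    metadata: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Score every metric column against mat P and the lat/long surface.

    Returns one row per metric with slope, adjusted R² and p of the
    metric–log₂(mat P) regression, the lat/long adjusted R², the metric
    metadata, and the three within-group rank columns.
    """
    rows = []
    for metric in metric_values.columns:
        y = metric_values[metric]
        try:
            slope, adj_r2, p = fit_metric_gradient(y, samples["mat_p"])
        except ValueError:
            slope = adj_r2 = p = np.nan
        try:
            ll = latlong_model(y, samples["latitude"], samples["longitude"])
        except (ValueError, KeyError):
            ll = np.nan
        rows.append(
            {"metric": metric, "slope": slope, "adj_r2": adj_r2,
             "p_value": p, "adj_r2_latlong": ll}
        )
    perf = pd.DataFrame(rows).merge(metadata, on="metric", how="left")
    return grouped_ranks(perf)


def grouped_ranks(perf: pd.DataFrame) -> pd.DataFrame:
    """Add the three within-group rank columns for the 24 trait metrics.

    ``rank_type`` ranks the 4 metric types (1 = lowest adj R²) within each
    source × trait group; ``rank_source`` ranks the 3 sources within type ×
    trait; ``rank_trait`` ranks the 2 traits within type × source. Ties are
    mid-ranked. Diversity/WAM rows get NaN ranks.
    """
    perf = perf.copy()
    trait_rows = perf["source"].isin(["literature", "regression", "titan"])
    for factor, group_cols in RANK_SCHEMES.items():
        col = f"rank_{factor}"
        perf[col] = np.nan
        sub = perf[trait_rows]
        perf.loc[trait_rows, col] = sub.groupby(list(group_cols))["adj_r2"].rank(
            method="average"
        )
    return perf


def family_anova(perf: pd.DataFrame, factor: str):
    """One-way ANOVA + Tukey HSD of trait-metric adjusted R² by a factor.

    ``factor`` is one of type/source/trait. Returns ``(F, p, tukey)`` where
    ``tukey`` is the pairwise comparison table (DataFrame).
    """
    if factor not in RANK_SCHEMES:
        raise ValueError(f"factor must be one of {sorted(RANK_SCHEMES)}")
    sub = perf[perf["source"].isin(["literature", "regression", "titan"])].dropna(
        subset=["adj_r2"]
    )
    groups = [g["adj_r2"].to_numpy() for _, g in sub.groupby(factor) if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 factor levels with >= 2 observations")
    if len(groups) < sub[factor].nunique():
        warnings.warn("dropped factor level(s) with < 2 observations")
    F, p = stats.f_oneway(*groups)
    if np.allclose(np.concatenate(groups), np.concatenate(groups).mean()):
        tukey = None
    else:
        res = pairwise_tukeyhsd(sub["adj_r2"].to_numpy(), sub[factor].to_numpy())
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return float(F), float(p), tukey


def family_kruskal(perf: pd.DataFrame, factor: str) -> tuple[float, float]:
    """Kruskal–Wallis test on the within-group ranks for one factor."""
    if factor not in RANK_SCHEMES:
        raise ValueError(f"factor must be one of {sorted(RANK_SCHEMES)}")
    col = f"rank_{factor}"
    sub = perf.dropna(subset=[col])
    groups = [g[col].to_numpy() for _, g in sub.groupby(factor) if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 factor levels with >= 2 observations")
    H, p = stats.kruskal(*groups)
    return float(H), float(p)
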