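"""Taxon trait assignment along the phosphorus gradient.

A taxon's *trait* is its association with low- or high-phosphorus conditions
(``lowP`` / ``highP`` / ``unassigned``). This module assigns traits by
regressing each taxon's relative abundance on log₂(mat P) — linear first,
then quadratic to catch unimodal/non-linear responders — and computes
abundance-weighted-average optima u_i and tolerances t_i for every taxon.
TITAN-based assignment lives in :mod:`periphyton.titan`; literature
assignments are user-supplied. The three sources are merged into one
long-form trait table with a disagreement report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import SOURCES
from .standardize import relative_abundance

__all__ = [
    "occurrence_filter",
    "assign_traits_regression",
    "GradientTraitClassifier",
    "wa_optimum_tolerance",
    "wa_table",
    "merge_trait_sources",
]


def occurrence_filter(counts: pd.DataFrame, min_occurrences: int = 5) -> pd.Index:
    """Taxa present (count > 0) in at least ``min_occurrences`` samples.

    The boundary is inclusive: a taxon in exactly ``min_occurrences`` samples
    is retained.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    n_occ = (counts > 0).sum(axis=1)
    return counts.index[n_occ >= min_occurrences]


def _polyfit_pvalues(y: np.ndarray, x: np.ndarray):
    """Linear slope (sign, p) and quadratic overall-F p plus endpoint sign."""
    n = len(x)
    # degree 1: slope t-test
    res = stats.linregress(x, y)
    lin_sign = np.sign(res.slope)
    lin_p = res.pvalue
    # degree 2: overall F against the intercept-only model
    X = np.column_stack([np.ones(n), x, x * x])
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df_model, df_resid = 2, n - 3
    if tss <= 0 or rss <= 0 or df_resid <= 0:
        quad_p = 1.0 if tss <= 0 else 0.0
    else:
        F = ((tss - rss) / df_model) / (rss / df_resid)
        quad_p = float(stats.f.sf(F, df_model, df_resid))
    ends = np.polyval(beta[::-1], [x.min(), x.max()])
    quad_sign = np.sign(ends[1] - ends[0])
    return lin_sign, lin_p, quad_sign, quad_p


def assign_traits_regression(
    proportions: np.ndarray, log2_mat_p: np.ndarray, alpha: float = 0.05
) -> str:
    """Classify one taxon's gradient response as lowP / highP / unassigned.

    Linear regression of relative abundance on log₂(mat P) is tried first: a
    significant negative slope → ``lowP``, positive → ``highP``. If the linear
    slope is not significant, a quadratic model is fitted and, when its
    overall F-test is significant, the trait is the sign of the fitted change
    across the gradient (value at the gradient maximum minus the minimum).
    Otherwise ``unassigned``.
    """
    y = np.asarray(proportions, dtype=float)
    x = np.asarray(log2_mat_p, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("gradient is constant; traits undefined")
    if len(x) < 4:
        raise ValueError("need at least 4 samples for quadratic fit")
    lin_sign, lin_p, quad_sign, quad_p = _polyfit_pvalues(y, x)
    if lin_p < alpha and lin_sign != 0:
        return "lowP" if lin_sign < 0 else "highP"
    if quad_p < alpha and quad_sign != 0:
        return "lowP" if quad_sign < 0 else "highP"
    return "unassigned"


class GradientTraitClassifier(BaseEstimator):
    """Assign lowP/highP traits to taxa by regression on log₂(mat P).

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for both the linear slope test and the quadratic
        overall F-test (applied sequentially, quadratic only when the linear
        test is not significant).
    min_occurrences : int, default 5
        Occurrence filter; taxa in fewer samples stay ``unassigned``.

    Attributes
    ----------
    trait_table_ : pandas.DataFrame
        Long-form rows (taxon, source="regression", trait, n_occurrences,
        optimum, tolerance) for every taxon in the input. Optima/tolerances
        are filled by :func:`wa_table` on the raw (unlogged) gradient.
    """

    def __init__(self, alpha: float = 0.05, min_occurrences: int = 5):
        self.alpha = alpha
        self.min_occurrences = min_occurrences

    def fit(self, counts: pd.DataFrame, mat_p):
        mat_p = np.asarray(mat_p, dtype=float)
        if (mat_p <= 0).any() or not np.isfinite(mat_p).all():
            raise ValueError("mat P must be positive and finite")
        props = relative_abundance(counts).to_numpy()
        x = np.log2(mat_p)
        keep = set(occurrence_filter(counts, self.min_occurrences))
        traits = []
        for i, taxon in enumerate(counts.index):
            if taxon in keep:
                traits.append(assign_traits_regression(props[i], x, self.alpha))
            else:
                traits.append("unassigned")
        wa = wa_table(counts, mat_p)
        self.trait_table_ = pd.DataFrame(
            {
                "taxon": counts.index,
                "source": "regression",
                "trait": traits,
                "n_occurrences": (counts > 0).sum(axis=1).to_numpy(),
                "optimum": wa["optimum"].to_numpy(),
                "tolerance": wa["tolerance"].to_numpy(),
            }
        )
        return self

    def predict(self, counts: pd.DataFrame) -> pd.Series:
        """Trait labels for the taxa seen in :meth:`fit` (by taxon id)."""
        table = self.trait_table_.set_index("taxon")["trait"]
        return table.reindex(counts.index, fill_value="unassigned")


def wa_optimum_tolerance(abundances, x) -> tuple[float, float]:
    """Weighted-average optimum and tolerance of one taxon.

    u_i = Σ_j y_ij x_j / Σ_j y_ij  (abundance-weighted mean of the gradient);
    t_i = sqrt(Σ_j y_ij (x_j − u_i)² / Σ_j y_ij)  (weighted SD).
    """
    y = np.asarray(abundances, dtype=float)
    x = np.asarray(x, dtype=float)
    w = y.sum()
    if w <= 0:
        raise ValueError("all-zero abundance; optimum undefined")
    u = float((y * x).sum() / w)
    t = float(np.sqrt((y * (x - u) ** 2).sum() / w))
    return u, t


def wa_table(counts: pd.DataFrame, mat_p, log2_gradient: bool = False) -> pd.DataFrame:
    """Weighted-average optima/tolerances for **all** taxa (no occurrence filter).

    Computed on relative abundances so near-equal rarefied totals weight
    samples equally. By default the gradient is raw mat P (µg g⁻¹); set
    ``log2_gradient`` for log-space optima.
    """
    x = np.asarray(mat_p, dtype=float)
    if log2_gradient:
        x = np.log2(x)
    props = relative_abundance(counts)
    rows = []
    for taxon in counts.index:
        y = props.loc[taxon].to_numpy()
        if y.sum() > 0:
            u, t = wa_optimum_tolerance(y, x)
        else:
            u, t = np.nan, np.nan
        rows.append((u, t))
    return pd.DataFrame(rows, index=counts.index, columns=["optimum", "tolerance"])


def merge_trait_sources(
    regression: pd.DataFrame | None = None,
    titan: pd.DataFrame | None = None,
    literature: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-source trait tables into one long table + disagreement report.

    Each input is a long-form table with at least (taxon, trait); its
    ``source`` column is overwritten with its argument name. The output has
    one row per taxon × source over the union of taxa (absent combinations
    are ``unassigned``). The report lists taxa given *both* lowP and highP by
    different sources.
    """
    inputs = {"regression": regression, "titan": titan, "literature": literature}
    frames = []
    taxa: list = []
    for source, table in inputs.items():
        if table is None or len(table) == 0:
            continue
        if table.duplicated("taxon").any():
            raise ValueError(f"duplicate taxon rows in {source} table")
        t = table.copy()
        t["source"] = source
        frames.append(t)
        taxa.extend(t["taxon"].tolist())
    taxa = list(dict.fromkeys(taxa))  # preserve first-seen order
    grid = pd.MultiIndex.from_product([taxa, SOURCES], names=["taxon", "source"])
    merged = (
        pd.concat(frames, ignore_index=True)
        .set_index(["taxon", "source"])
        .reindex(grid)
        .reset_index()
    )
    merged["trait"] = merged["trait"].fillna("unassigned")
    wide = merged.pivot(index="taxon", columns="source", values="trait")
    conflict = wide.apply(
        lambda r: ("lowP" in set(r)) and ("highP" in set(r)), axis=1
    )
    report = wide.loc[conflict.to_numpy()].reset_index()
    return merged, report
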