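"""Candidate management benchmarks along the mat P gradient.

Three lines of evidence are combined: (1) permutation-tested regression-tree
changepoints of each benchmark metric against mat P, (2) mat P percentiles of
low-P sample groups from Bray–Curtis hierarchical clustering, and (3) the
TITAN community sum(z) changepoints. A fourth, descriptive line reports mat P
percentiles within user-designated minimally disturbed regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from ._rng import substream
from .standardize import relative_abundance

__all__ = [
    "bray_curtis",
    "hierarchical_groups",
    "AssemblageClusterer",
    "tree_changepoints",
    "TreeChangepointRegressor",
    "ChangepointResult",
    "ClusterResult",
    "benchmark_metric_subset",
    "benchmark_report",
]


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Bray–Curtis dissimilarity on relative abundances.

    BC(j,k) = Σ_i |y_ij − y_ik| / Σ_i (y_ij + y_ik); symmetric, zero
    diagonal, bounded in [0, 1].
    """
    props = relative_abundance(counts)
    d = squareform(pdist(props.T.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


@dataclass
class ClusterResult:
    """Hierarchical grouping of samples with per-group mat P percentiles."""

    labels: pd.Series                      # sample → group id (1-based)
    cut_height: float
    linkage_method: str
    group_summary: pd.DataFrame = None     # per-group size, mat P percentiles,
                                           # mean within-group dissimilarity
    linkage_matrix: np.ndarray = field(default=None, repr=False)


def hierarchical_groups(
    dissimilarity: pd.DataFrame,
    cut_height: float = 0.75,
    linkage: str = "average",
    mat_p=None,
) -> ClusterResult:
    """Agglomerate samples and cut the tree at a dissimilarity level.

    Groups are numbered 1..G in order of increasing median mat P when mat P
    is supplied (else by first occurrence). The summary reports, per group,
    the 50th/75th/90th mat P percentiles (linear interpolation between order
    statistics) and the mean pairwise within-group dissimilarity.
    """
    D = dissimilarity.to_numpy()
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    max_h = Z[:, 2].max() if len(Z) else 0.0
    if cut_height < 0 or cut_height > max(max_h, 0.0) + 1.0:
        raise ValueError(f"cut height {cut_height} outside [0, {max_h:.3f}]")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=dissimilarity.index, name="group")
    if mat_p is not None:
        mat_p = pd.Series(np.asarray(mat_p, dtype=float), index=dissimilarity.index)
        order = labels.groupby(labels).apply(
            lambda g: mat_p[g.index].median()
        ).sort_values().index
        remap = {old: new for new, old in enumerate(order, start=1)}
        labels = labels.map(remap)
    rows = []
    for g in sorted(labels.unique()):
        members = labels.index[labels == g]
        idx = [dissimilarity.index.get_loc(m) for m in members]
        within = (
            D[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].mean()
            if len(idx) > 1
            else 0.0
        )
        row = {"group": g, "n": len(members), "mean_within_dissimilarity": within}
        if mat_p is not None:
            vals = mat_p[members].dropna()
            for q in (50, 75, 90):
                row[f"mat_p_p{q}"] = (
                    float(np.percentile(vals, q)) if len(vals) else np.nan
                )
        rows.append(row)
    return ClusterResult(labels, cut_height, linkage, pd.DataFrame(rows), Z)


class AssemblageClusterer(BaseEstimator):
    """Bray–Curtis hierarchical clustering of samples (sklearn-style).

    Attributes after ``fit``: ``dissimilarity_``, ``labels_``, ``result_``.
    """

    def __init__(self, cut_height: float = 0.75, linkage: str = "average"):
        self.cut_height = cut_height
        self.linkage = linkage

    def fit(self, counts: pd.DataFrame, mat_p=None):
        self.dissimilarity_ = bray_curtis(counts)
        self.result_ = hierarchical_groups(
            self.dissimilarity_, self.cut_height, self.linkage, mat_p
        )
        self.labels_ = self.result_.labels
        return self


@dataclass
class ChangepointResult:
    """Recursive significant SSE-minimising splits of a metric along mat P."""

    breakpoints: list            # sorted µg g⁻¹ midpoints
    p_values: list               # permutation p per accepted split
    sse_reductions: list
    group_means: list            # (mean below, mean above) per split


def _best_split(x_sorted: np.ndarray, Y: np.ndarray, min_leaf: int):
    """Best SSE-reducing split for each row of ``Y`` (columns in x order).

    Returns ``(best_k, best_reduction)`` arrays; k is the left-group size.
    Ties in x are kept together; admissible splits need ``min_leaf`` samples
    per side. Rows with no admissible split get reduction −inf.
    """
    n = len(x_sorted)
    ks = np.arange(min_leaf, n - min_leaf + 1)
    ks = ks[x_sorted[ks - 1] < x_sorted[ks]]
    if len(ks) == 0:
        m = Y.shape[0]
        return np.full(m, -1), np.full(m, -np.inf)
    cum = np.cumsum(Y, axis=1)
    cum2 = np.cumsum(Y**2, axis=1)
    tot, tot2 = cum[:, -1:], cum2[:, -1:]
    k = ks[None, :].astype(float)
    sum_l = cum[:, ks - 1]
    sse_l = cum2[:, ks - 1] - sum_l**2 / k
    sum_r = tot - sum_l
    sse_r = (tot2 - cum2[:, ks - 1]) - sum_r**2 / (n - k)
    sse_tot = (tot2 - tot**2 / n).ravel()
    reduction = sse_tot[:, None] - (sse_l + sse_r)
    best = np.argmax(reduction, axis=1)
    return ks[best], reduction[np.arange(Y.shape[0]), best]


def tree_changepoints(
    y,
    x,
    min_leaf: int = 5,
    max_depth: int = 3,
    n_perm: int = 999,
    alpha: float = 0.01,
    seed=None,
) -> ChangepointResult:
    """Permutation-tested regression-tree changepoints of ``y`` along ``x``.

    Recursively splits the gradient at the SSE-minimising breakpoint; each
    split is kept only if its SSE reduction beats ``alpha`` against
    ``n_perm`` within-node permutations of ``y``. Breakpoints are reported
    at the midpoint of the straddling x values, in increasing order.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} observations")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    found = []

    def recurse(lo: int, hi: int, depth: int, node: int):
        n = hi - lo
        if depth >= max_depth or n < 2 * min_leaf:
            return
        xseg, yseg = xs[lo:hi], ys[lo:hi]
        if np.ptp(yseg) == 0:
            return
        k, red = _best_split(xseg, yseg[None, :], min_leaf)
        k, red = int(k[0]), float(red[0])
        if not np.isfinite(red) or red <= 0:
            return
        rng = substream(seed, "treeperm", node)
        perms = rng.permuted(np.broadcast_to(yseg, (n_perm, n)).copy(), axis=1)
        _, perm_red = _best_split(xseg, perms, min_leaf)
        p = float((1 + (perm_red >= red).sum()) / (n_perm + 1))
        if p > alpha:
            return
        found.append(
            {
                "breakpoint": float((xseg[k - 1] + xseg[k]) / 2.0),
                "p": p,
                "reduction": red,
                "means": (float(yseg[:k].mean()), float(yseg[k:].mean())),
            }
        )
        recurse(lo, lo + k, depth + 1, 2 * node + 1)
        recurse(lo + k, hi, depth + 1, 2 * node + 2)

    recurse(0, len(xs), 0, 0)
    found.sort(key=lambda d: d["breakpoint"])
    return ChangepointResult(
        [f["breakpoint"] for f in found],
        [f["p"] for f in found],
        [f["reduction"] for f in found],
        [f["means"] for f in found],
    )


class TreeChangepointRegressor(BaseEstimator):
    """sklearn-style wrapper over :func:`tree_changepoints`.

    ``fit(x, y)`` stores ``result_`` and ``breakpoints_``; ``predict(x)``
    returns the fitted piecewise-constant group means.
    """

    def __init__(
        self,
        min_leaf: int = 5,
        max_depth: int = 3,
        n_perm: int = 999,
        alpha: float = 0.01,
        random_state=None,
    ):
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.n_perm = n_perm
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        self.result_ = tree_changepoints(
            y,
            x,
            min_leaf=self.min_leaf,
            max_depth=self.max_depth,
            n_perm=self.n_perm,
            alpha=self.alpha,
            seed=self.random_state,
        )
        self.breakpoints_ = self.result_.breakpoints
        edges = [-np.inf] + self.breakpoints_ + [np.inf]
        self.segment_means_ = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (x > lo) & (x <= hi)
            self.segment_means_.append(float(y[mask].mean()) if mask.any() else np.nan)
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float).ravel()
        idx = np.searchsorted(self.breakpoints_, x, side="left")
        return np.asarray(self.segment_means_)[idx]


def benchmark_metric_subset(metadata: pd.DataFrame) -> list[str]:
    """The 13 benchmark metrics: 3 diversity + 2 WAM + 8 TITAN-trait metrics.

    Literature- and regression-trait metrics are excluded as redundant with
    the TITAN-trait metrics.
    """
    keep = metadata["source"].isin(["titan", "-"])
    return metadata.loc[keep, "metric"].tolist()


def benchmark_report(
    metric_values: pd.DataFrame,
    metadata: pd.DataFrame,
    mat_p,
    titan_profile=None,
    cluster_result: ClusterResult | None = None,
    minimally_disturbed=None,
    cutoffs=(200.0, 500.0),
    tree_kwargs=None,
    seed=None,
) -> pd.DataFrame:
    """Assemble the candidate-benchmark table from all lines of evidence.

    One row per (method, quantity) with the candidate mat P value in
    µg g⁻¹. Methods with missing inputs are omitted with a warning.
    ``minimally_disturbed`` is a boolean mask (or sample-id list) selecting
    reference samples whose mat P percentiles are reported descriptively.
    """
    mat_p = pd.Series(
        np.asarray(mat_p, dtype=float), index=metric_values.index
    )
    rows = []
    tree_kwargs = dict(tree_kwargs or {})
    subset = [m for m in benchmark_metric_subset(metadata) if m in metric_values]
    for metric in subset:
        try:
            res = tree_changepoints(
                metric_values[metric], mat_p, seed=seed, **tree_kwargs
            )
        except ValueError:
            warnings.warn(f"changepoint analysis skipped for {metric}")
            continue
        for bp, p in zip(res.breakpoints, res.p_values):
            rows.append(
                {
                    "method": "tree_changepoint",
                    "quantity": metric,
                    "mat_p": bp,
                    "detail": f"p={p:.4g}",
                }
            )
    if cluster_result is not None and cluster_result.group_summary is not None:
        gs = cluster_result.group_summary
        if "mat_p_p75" in gs:
            low = gs.sort_values("mat_p_p75").iloc[0]
            for q in (50, 75, 90):
                rows.append(
                    {
                        "method": "cluster_percentile",
                        "quantity": f"group{int(low['group'])}_p{q}",
                        "mat_p": low[f"mat_p_p{q}"],
                        "detail": f"n={int(low['n'])}",
                    }
                )
    else:
        warnings.warn("cluster result missing; cluster benchmarks omitted")
    if titan_profile is not None and np.isfinite(titan_profile.changepoint_minus):
        rows.append(
            {
                "method": "titan_sum_z",
                "quantity": "community_z_minus",
                "mat_p": titan_profile.changepoint_minus,
                "detail": "argmax sum(z-)",
            }
        )
        if np.isfinite(titan_profile.changepoint_plus):
            rows.append(
                {
                    "method": "titan_sum_z",
                    "quantity": "community_z_plus",
                    "mat_p": titan_profile.changepoint_plus,
                    "detail": "argmax sum(z+)",
                }
            )
    else:
        warnings.warn("TITAN profile missing; sum(z) benchmark omitted")
    if minimally_disturbed is not None:
        ref = mat_p.loc[minimally_disturbed].dropna()
        if len(ref):
            for q, name in ((50, "median"), (75, "p75"), (90, "p90")):
                rows.append(
                    {
                        "method": "minimally_disturbed",
                        "quantity": name,
                        "mat_p": float(np.percentile(ref, q)),
                        "detail": f"n={len(ref)}",
                    }
                )
            for c in cutoffs:
                rows.append(
                    {
                        "method": "minimally_disturbed",
                        "quantity": f"fraction_below_{c:g}",
                        "mat_p": float((ref < c).mean()),
                        "detail": "fraction of samples",
                    }
                )
    return pd.DataFrame(rows)
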