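"""The per-sample metric suite: trait metrics, diversity, and WA inference.

For each trait source (literature, regression, TITAN) and each trait (lowP,
highP) four metric types are computed, giving the 2 × 3 × 4 = 24 trait
metrics:

* **PropValves** — proportion of valves belonging to trait-*t* taxa,
  Σ v_ijt / V_j, where V_j counts valves of trait-assigned taxa only;
* **PropTaxa** — proportion of trait-assigned taxa that carry trait *t*,
  t_tj / T_j;
* **noTaxa** — number of taxa present with trait *t*;
* **RlogA** — relative log abundance: each taxon contributes ln(valves), and
  the metric is the trait-*t* share of that log-abundance,
  RlogA_jt = Σ_{i∈t} ln(A_ij) / Σ_{i∈assigned} ln(A_ij). Taxa counted once
  contribute ln(1) = 0 — the literal published formula, no +1 shift.

Unassigned taxa are excluded from every denominator. Three diversity metrics
(richness, Shannon H, Pielou J) and two weighted-average inferred-P metrics
(simple and tolerance-downweighted) complete the 29-metric suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import SOURCES

__all__ = [
    "simple_trait_metrics",
    "rloga_metric",
    "diversity_metrics",
    "wam_infer",
    "WeightedAverageModel",
    "build_metric_matrix",
    "metric_metadata",
    "TRAIT_METRIC_TYPES",
]

TRAIT_METRIC_TYPES = ("PropValves", "PropTaxa", "noTaxa", "RlogA")


def _trait_lookup(trait_rows: pd.DataFrame) -> pd.Series:
    """taxon → trait for one source's long-form rows."""
    if trait_rows.duplicated("taxon").any():
        raise ValueError("duplicate taxon rows for one trait source")
    return trait_rows.set_index("taxon")["trait"]


def simple_trait_metrics(sample_counts: pd.Series, trait_rows: pd.DataFrame) -> dict:
    """PropValves, PropTaxa and noTaxa for both traits in one sample.

    Denominators (V_j, T_j) cover trait-assigned taxa only. With no
    trait-assigned taxa present the two proportions are undefined (NaN, with
    a warning) and noTaxa is 0.
    """
    traits = _trait_lookup(trait_rows).reindex(sample_counts.index, fill_value="unassigned")
    present = sample_counts > 0
    out = {}
    assigned = present & traits.isin(["lowP", "highP"])
    v_j = sample_counts[assigned].sum()
    t_j = int(assigned.sum())
    for trait in ("lowP", "highP"):
        mask = present & (traits == trait)
        out[f"noTaxa_{trait}"] = int(mask.sum())
        if t_j == 0:
            out[f"PropValves_{trait}"] = np.nan
            out[f"PropTaxa_{trait}"] = np.nan
        else:
            out[f"PropValves_{trait}"] = float(sample_counts[mask].sum() / v_j)
            out[f"PropTaxa_{trait}"] = float(mask.sum() / t_j)
    if t_j == 0:
        warnings.warn("no trait-assigned taxa present; proportions undefined")
    return out


def rloga_metric(sample_counts: pd.Series, trait_rows: pd.DataFrame) -> dict:
    """Relative log abundance of each trait in one sample.

    Computed as the published double ratio: per-taxon shares
    RlogA_ijt = ln(A_ijt) / Σ ln(A_ij) are summed for the trait and divided
    by the summed shares of all assigned taxa (algebraically the ratio of
    log-count sums). Requires at least one assigned taxon with ≥ 2 valves,
    otherwise the denominator Σ ln(A) is zero and the value is NaN.
    """
    traits = _trait_lookup(trait_rows).reindex(sample_counts.index, fill_value="unassigned")
    present = sample_counts > 0
    assigned = present & traits.isin(["lowP", "highP"])
    log_a = np.log(sample_counts[assigned].astype(float))
    denom = log_a.sum()
    if denom <= 0:
        warnings.warn("all assigned taxa at count <= 1; RlogA undefined")
        return {"RlogA_lowP": np.nan, "RlogA_highP": np.nan}
    shares = log_a / denom                      # RlogA_ijt, the double ratio
    total_share = shares.sum()                  # = 1 by construction
    out = {}
    for trait in ("lowP", "highP"):
        mask = traits[assigned.index[assigned]] == trait
        out[f"RlogA_{trait}"] = float(shares[mask[mask].index].sum() / total_share)
    return out


def diversity_metrics(sample_counts: pd.Series | np.ndarray) -> dict:
    """Richness S, Shannon H (natural log) and Pielou evenness J = H/ln S.

    J is undefined (NaN) for single-taxon samples.
    """
    y = np.asarray(sample_counts, dtype=float)
    total = y.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = y[y > 0] / total
    s = int((y > 0).sum())
    h = float(-(p * np.log(p)).sum())
    j = h / np.log(s) if s > 1 else np.nan
    return {"richness": s, "shannon": h, "evenness": j}


def wam_infer(
    sample_counts: pd.Series,
    optima: pd.Series,
    tolerances: pd.Series | None = None,
    variant: str = "simple",
) -> float:
    """Weighted-average inferred mat P for one sample.

    simple: x̂ = Σ y_i u_i / Σ y_i. tol: abundances are additionally
    downweighted by t_i², with zero tolerances replaced by the smallest
    positive tolerance observed. Taxa without an optimum are ignored; with
    none available the result is NaN.
    """
    if variant not in ("simple", "tol"):
        raise ValueError("variant must be 'simple' or 'tol'")
    y = sample_counts.astype(float)
    u = optima.reindex(y.index)
    usable = (y > 0) & u.notna()
    if variant == "tol":
        t = tolerances.reindex(y.index).astype(float)
        pos = t[t > 0]
        floor = pos.min() if len(pos) else np.nan
        t = t.where(t > 0, floor)
        usable &= t.notna()
    if not usable.any():
        return np.nan
    w = y[usable]
    if variant == "tol":
        w = w / t[usable] ** 2
    return float((w * u[usable]).sum() / w.sum())


class WeightedAverageModel(BaseEstimator):
    """WA transfer function: calibrate taxon optima, infer sample mat P.

    ``fit`` computes abundance-weighted optima u_i and tolerances t_i for all
    taxa from a calibration count matrix and its mat P vector (no occurrence
    filter — the model is most precise using all taxa). ``predict`` returns
    the abundance-weighted mean optimum of each sample's taxa.

    Parameters
    ----------
    variant : {"simple", "tol"}
        Plain WA or tolerance-downweighted WA.
    log2_gradient : bool, default False
        Calibrate/infer on log₂(mat P) instead of raw µg g⁻¹.
    """

    def __init__(self, variant: str = "simple", log2_gradient: bool = False):
        self.variant = variant
        self.log2_gradient = log2_gradient

    def fit(self, counts: pd.DataFrame, mat_p):
        from .traits import wa_table

        tab = wa_table(counts, mat_p, log2_gradient=self.log2_gradient)
        self.optima_ = tab["optimum"]
        self.tolerances_ = tab["tolerance"]
        return self

    def predict(self, counts: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [
                wam_infer(
                    counts[c], self.optima_, self.tolerances_, variant=self.variant
                )
                for c in counts.columns
            ],
            index=counts.columns,
            name=f"WAM_{self.variant}",
        )


def metric_metadata() -> pd.DataFrame:
    """Metadata for the full 29-metric suite (type, source, trait)."""
    rows = []
    for source in SOURCES:
        for trait in ("lowP", "highP"):
            for mtype in TRAIT_METRIC_TYPES:
                rows.append(
                    {
                        "metric": f"{mtype}_{trait}_{source}",
                        "type": mtype,
                        "source": source,
                        "trait": trait,
                    }
                )
    for m in ("richness", "shannon", "evenness"):
        rows.append({"metric": m, "type": m, "source": "-", "trait": "-"})
    for m in ("WAM_simple", "WAM_tol"):
        rows.append({"metric": m, "type": m, "source": "-", "trait": "-"})
    return pd.DataFrame(rows)


def build_metric_matrix(
    counts: pd.DataFrame,
    trait_table: pd.DataFrame,
    optima: pd.Series | None = None,
    tolerances: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the 29-metric suite for every sample.

    Parameters
    ----------
    counts : taxa × samples standardized counts
    trait_table : long-form (taxon, source, trait) covering the three sources;
        a source with no assigned taxa yields NaN columns with a warning.
    optima, tolerances : per-taxon WA parameters for the two WAM metrics;
        derived from ``trait_table`` rows when present there, else required.

    Returns
    -------
    (values, metadata) : samples × 29 DataFrame and the metadata table.
    """
    meta = metric_metadata()
    if optima is None and "optimum" in trait_table:
        first = trait_table.dropna(subset=["optimum"]).drop_duplicates("taxon")
        optima = first.set_index("taxon")["optimum"]
        tolerances = first.set_index("taxon").get("tolerance")
    if optima is None:
        raise ValueError("optima required for WAM metrics")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        by_source = {
            s: trait_table[trait_table["source"] == s] for s in SOURCES
        }
        for s, rows_s in by_source.items():
            if not rows_s["trait"].isin(["lowP", "highP"]).any():
                warnings.warn(f"trait source {s!r} has no assigned taxa; NaN metrics")
        for sample in counts.columns:
            sc = counts[sample]
            row = {}
            for source, rows_s in by_source.items():
                if rows_s["trait"].isin(["lowP", "highP"]).any():
                    vals = simple_trait_metrics(sc, rows_s) | rloga_metric(sc, rows_s)
                else:
                    vals = {
                        f"{m}_{t}": np.nan
                        for m in TRAIT_METRIC_TYPES
                        for t in ("lowP", "highP")
                    }
                row.update({f"{k}_{source}": v for k, v in vals.items()})
            row.update(diversity_metrics(sc))
            row["WAM_simple"] = wam_infer(sc, optima, tolerances, "simple")
            row["WAM_tol"] = wam_infer(sc, optima, tolerances, "tol")
            rows.append(row)
    values = pd.DataFrame(rows, index=counts.columns)[meta["metric"].tolist()]
    return values, meta
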