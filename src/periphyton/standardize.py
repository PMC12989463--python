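"""Count-effort standardisation (rarefaction) and relative abundances.

Valve counts vary above the nominal 600-valve counting effort, so samples are
standardised by uniform random subsampling of valves without replacement
(equivalent to ranking every counted valve by a random number and keeping the
lowest ``target``). The subsample of one sample is a multivariate
hypergeometric draw, which numpy provides directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import as_rng, substream

__all__ = ["Rarefier", "rarefy_sample", "rarefy_matrix", "relative_abundance"]


def rarefy_sample(counts, target: int, seed=None) -> tuple[np.ndarray, bool]:
    """Subsample one sample's counts to ``target`` valves without replacement.

    Returns ``(standardized_counts, was_subsampled)``. Samples already at or
    under the target are returned unchanged with a warning.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts < 0).any() or (counts != np.floor(counts)).any():
        raise ValueError("counts must be a 1-D non-negative integer vector")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if total <= target:
        if total < target:
            warnings.warn(
                f"sample total {total} below target {target}; returned unchanged"
            )
        return counts.copy(), False
    rng = as_rng(seed)
    return rng.multivariate_hypergeometric(counts, target), True


class Rarefier(BaseEstimator, TransformerMixin):
    """Standardise every sample of a count matrix to a fixed counting effort.

    Parameters
    ----------
    target : int, default 600
        Valves to retain per sample (the counting effort).
    random_state : int or None
        Master seed; each sample uses an independent substream keyed by its
        position, so results do not depend on how many samples precede it
        drawing random numbers.

    Attributes
    ----------
    original_totals_ : pandas.Series
        Pre-standardisation valve totals per sample.
    subsampled_ : pandas.Series of bool
        Whether each sample was actually subsampled (False = already ≤ target,
        kept unchanged and flagged).
    """

    def __init__(self, target: int = 600, random_state=None):
        self.target = target
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if self.target < 1:
            raise ValueError("target must be >= 1")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Rarefy a taxa-by-samples count DataFrame."""
        self.fit(X)
        out = np.empty(X.shape, dtype=np.int64)
        totals = X.sum(axis=0)
        flags = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for j, sample in enumerate(X.columns):
                rng = substream(self.random_state, "rarefy", j)
                out[:, j], sub = rarefy_sample(
                    X.iloc[:, j].to_numpy(), self.target, rng
                )
                flags.append(sub)
        under = totals[totals < self.target]
        if len(under):
            warnings.warn(
                f"{len(under)} sample(s) under the {self.target}-valve target "
                f"kept unchanged: {under.index.tolist()}"
            )
        self.original_totals_ = totals
        self.subsampled_ = pd.Series(flags, index=X.columns)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def rarefy_matrix(counts: pd.DataFrame, target: int = 600, seed=None) -> pd.DataFrame:
    """Functional wrapper over :class:`Rarefier`."""
    return Rarefier(target=target, random_state=seed).transform(counts)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    totals = counts.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"empty sample(s): {empty.index.tolist()}")
    return counts / totals
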