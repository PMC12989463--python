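"""Threshold Indicator Taxa ANalysis (TITAN).

For each taxon, TITAN scans candidate changepoints along a continuous
stressor gradient (mat P), splits samples into a low-x and a high-x group at
each candidate, and computes the Dufrêne–Legendre indicator value (IndVal,
0–100: specificity × fidelity) of the taxon on each side. The observed
IndVal is standardised against permutations of the group labels into a z
score; the selected changepoint maximises z. Taxa whose indicator value
decreases with the gradient are *z−* (lowP) taxa, increasers are *z+*
(highP). Bootstrap resampling yields *purity* (direction consistency) and
*reliability* (significance consistency), and summing z scores of pure,
reliable taxa by direction over candidates gives community-level changepoint
profiles.

Permutation p-values here are selection-adjusted: every permutation's IndVal
curve is z-scored with the permutation ensemble's per-candidate mean/sd and
its maximum over candidates is compared with the observed maximum z, so the
test accounts for choosing the best candidate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._rng import as_rng, substream
from .standardize import relative_abundance
from .traits import wa_table

logger = logging.getLogger(__name__)

__all__ = [
    "indval",
    "titan_taxon",
    "titan_bootstrap",
    "community_profile",
    "traits_from_titan",
    "TitanAnalyzer",
    "TitanTaxonResult",
    "CommunityZProfile",
]


def indval(y, groups) -> tuple[float, float]:
    """Dufrêne–Legendre indicator values of one taxon for a binary partition.

    specificity A_g = mean abundance in g / Σ_groups mean abundance;
    fidelity B_g = fraction of samples in g where the taxon occurs;
    IndVal_g = 100 · A_g · B_g. Returns ``(score_left, score_right)`` where
    "left" is ``groups == 0``.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups)
    nl = int((g == 0).sum())
    nr = int((g != 0).sum())
    if nl == 0 or nr == 0:
        raise ValueError("both groups must be nonempty")
    if not (y > 0).any():
        warnings.warn("all-zero abundance vector; IndVal = 0 for both groups")
        return 0.0, 0.0
    mean_l = y[g == 0].mean()
    mean_r = y[g != 0].mean()
    a_l = mean_l / (mean_l + mean_r)
    b_l = (y[g == 0] > 0).mean()
    b_r = (y[g != 0] > 0).mean()
    return 100.0 * a_l * b_l, 100.0 * (1.0 - a_l) * b_r


def _candidates(x_sorted: np.ndarray, min_split: int) -> np.ndarray:
    """Boundary indices k (left group = first k sorted samples).

    Tied gradient values are kept on one side, so boundaries fall only
    between distinct x values, with at least ``min_split`` samples per side.
    """
    n = len(x_sorted)
    ks = np.arange(min_split, n - min_split + 1)
    return ks[x_sorted[ks - 1] < x_sorted[ks]]


def _indval_max_curves(Y: np.ndarray, ks: np.ndarray):
    """Max-side IndVal at every candidate for each row of ``Y``.

    ``Y`` is (m, n) with columns already in gradient order. Returns
    ``(iv_max, left_is_indicator)`` of shape (m, K).
    """
    n = Y.shape[1]
    cum = np.cumsum(Y, axis=1)
    cump = np.cumsum(Y > 0, axis=1)
    tot = cum[:, -1:]
    totp = cump[:, -1:]
    k = ks[None, :].astype(float)
    sum_l = cum[:, ks - 1]
    mean_l = sum_l / k
    mean_r = (tot - sum_l) / (n - k)
    denom = mean_l + mean_r
    with np.errstate(invalid="ignore", divide="ignore"):
        a_l = np.where(denom > 0, mean_l / denom, 0.0)
    b_l = cump[:, ks - 1] / k
    b_r = (totp - cump[:, ks - 1]) / (n - k)
    iv_l = 100.0 * a_l * b_l
    iv_r = 100.0 * (1.0 - a_l) * b_r
    left = iv_l >= iv_r
    return np.where(left, iv_l, iv_r), left


@dataclass
class TitanTaxonResult:
    """Per-taxon TITAN output (plus the z curve used for community sums)."""

    taxon: str
    direction: str            # "z-" (decreaser) or "z+" (increaser)
    changepoint: float        # µg g⁻¹, midpoint of the straddling x values
    indval: float             # observed IndVal at the selected candidate
    z: float                  # max standardised IndVal
    p: float                  # selection-adjusted permutation p
    candidates: np.ndarray = field(repr=False, default=None)
    z_curve: np.ndarray = field(repr=False, default=None)
    left_curve: np.ndarray = field(repr=False, default=None)
    purity: float = np.nan
    reliability: float = np.nan
    cp_quantiles: dict = field(default_factory=dict)


def titan_taxon(
    y,
    x,
    n_perm: int = 250,
    min_split: int = 5,
    seed=None,
    select_by: str = "z",
    taxon: str = "",
) -> TitanTaxonResult:
    """Locate one taxon's indicator-value changepoint along the gradient.

    At each candidate split (x ≤ c vs x > c, ties kept together, ≥
    ``min_split`` samples per side) the taxon's side is the group with the
    larger IndVal. z standardises that IndVal against ``n_perm`` random
    permutations of the labels; the selected changepoint maximises z (or raw
    IndVal with ``select_by="indval"``). Direction is *z−* when the indicator
    side at the selected candidate is the low-x group.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_split:
        raise ValueError(f"need at least {2 * min_split} samples, got {n}")
    if (y > 0).sum() < min_split:
        raise ValueError(
            f"taxon occurs in {(y > 0).sum()} samples; min_split={min_split}"
        )
    if select_by not in ("z", "indval"):
        raise ValueError("select_by must be 'z' or 'indval'")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ks = _candidates(xs, min_split)
    if len(ks) == 0:
        raise ValueError("no admissible candidate changepoints (too many ties)")

    iv_obs, left_obs = _indval_max_curves(ys[None, :], ks)
    iv_obs, left_obs = iv_obs[0], left_obs[0]

    rng = as_rng(seed)
    perms = rng.permuted(np.broadcast_to(ys, (n_perm, n)).copy(), axis=1)
    iv_perm, _ = _indval_max_curves(perms, ks)
    mu = iv_perm.mean(axis=0)
    sd = iv_perm.std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    z_curve = np.where(sd > 0, (iv_obs - mu) / safe, 0.0)
    z_perm = np.where(sd > 0, (iv_perm - mu) / safe, 0.0)

    sel = int(np.argmax(z_curve if select_by == "z" else iv_obs))
    z_max = float(z_curve[sel] if select_by == "z" else z_curve.max())
    p = float((1 + (z_perm.max(axis=1) >= z_curve.max()).sum()) / (n_perm + 1))
    k = ks[sel]
    cp = float((xs[k - 1] + xs[k]) / 2.0)
    candidates = (xs[ks - 1] + xs[ks]) / 2.0
    return TitanTaxonResult(
        taxon=taxon,
        direction="z-" if left_obs[sel] else "z+",
        changepoint=cp,
        indval=float(iv_obs[sel]),
        z=z_max,
        p=p,
        candidates=candidates,
        z_curve=z_curve,
        left_curve=left_obs,
    )


def titan_bootstrap(
    y,
    x,
    n_boot: int = 500,
    n_perm: int = 250,
    min_split: int = 5,
    seed=None,
    direction: str | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, dict]:
    """Bootstrap purity, reliability and changepoint quantiles for one taxon.

    Samples are resampled with replacement ``n_boot`` times; replicates in
    which the taxon occurs fewer than ``min_split`` times (or no candidate
    split exists) are redrawn up to 10 times, then counted as failures.
    purity = fraction of replicates reproducing the observed ``direction``;
    reliability = fraction with permutation p ≤ ``alpha``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if direction is None:
        direction = titan_taxon(
            y, x, n_perm=n_perm, min_split=min_split, seed=seed
        ).direction
    directions, ps, cps = [], [], []
    failures = 0
    for b in range(n_boot):
        rng = substream(seed, "boot", b)
        res = None
        for _ in range(10):
            idx = rng.integers(0, n, n)
            try:
                res = titan_taxon(
                    y[idx], x[idx], n_perm=n_perm, min_split=min_split, seed=rng
                )
                break
            except ValueError:
                res = None
        if res is None:
            failures += 1
            continue
        directions.append(res.direction)
        ps.append(res.p)
        cps.append(res.changepoint)
    if failures:
        logger.warning("%d of %d bootstrap replicates failed", failures, n_boot)
    if not directions:
        return np.nan, np.nan, {}
    purity = float(np.mean([d == direction for d in directions]))
    reliability = float(np.mean([p <= alpha for p in ps]))
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    quants = dict(zip(qs, np.quantile(cps, qs)))
    return purity, reliability, quants


@dataclass
class CommunityZProfile:
    """Summed z profiles by response direction over candidate changepoints."""

    candidates: np.ndarray
    sum_z_minus: np.ndarray
    sum_z_plus: np.ndarray
    changepoint_minus: float
    changepoint_plus: float
    boot_cum_minus: pd.Series | None = None   # cumulative freq of boot changepoints
    boot_cum_plus: pd.Series | None = None


def community_profile(
    results: list[TitanTaxonResult],
    purity_min: float = 0.95,
    reliability_min: float = 0.95,
) -> CommunityZProfile:
    """Sum per-taxon z curves by direction; argmax = community changepoint.

    Only taxa passing the purity/reliability filters contribute. Negative z
    values are clipped to zero before summing so the profiles are
    non-negative accumulations of indicator signal. Directions with no
    passing taxa yield an empty (all-zero) profile with a warning.
    """
    passing = [
        r
        for r in results
        if (np.isnan(r.purity) or r.purity >= purity_min)
        and (np.isnan(r.reliability) or r.reliability >= reliability_min)
    ]
    if not passing:
        warnings.warn("no taxa pass the purity/reliability filters")
        return CommunityZProfile(np.array([]), np.array([]), np.array([]), np.nan, np.nan)
    candidates = passing[0].candidates
    sums = {"z-": np.zeros(len(candidates)), "z+": np.zeros(len(candidates))}
    for r in passing:
        sums[r.direction] += np.clip(r.z_curve, 0.0, None)
    cps = {}
    for d in ("z-", "z+"):
        if sums[d].any():
            cps[d] = float(candidates[int(np.argmax(sums[d]))])
        else:
            warnings.warn(f"no taxa with direction {d} pass the filters")
            cps[d] = np.nan
    return CommunityZProfile(
        candidates, sums["z-"], sums["z+"], cps["z-"], cps["z+"]
    )


def traits_from_titan(
    taxon_results: pd.DataFrame,
    purity_min: float = 0.95,
    reliability_min: float = 0.95,
) -> pd.DataFrame:
    """Convert TITAN results to long-form trait rows (source = "titan").

    z− taxa passing both bootstrap filters become ``lowP``, z+ become
    ``highP``; everything else is ``unassigned``.
    """
    passing = (taxon_results["purity"].fillna(1.0) >= purity_min) & (
        taxon_results["reliability"].fillna(1.0) >= reliability_min
    )
    trait = np.where(
        passing & (taxon_results["direction"] == "z-"),
        "lowP",
        np.where(passing & (taxon_results["direction"] == "z+"), "highP", "unassigned"),
    )
    return pd.DataFrame(
        {
            "taxon": taxon_results["taxon"],
            "source": "titan",
            "trait": trait,
        }
    )


class TitanAnalyzer(BaseEstimator):
    """Full TITAN analysis of a count matrix along the mat P gradient.

    Parameters
    ----------
    n_perm : int, default 250
        Label permutations per candidate scan (z standardisation and p).
    n_boot : int, default 500
        Bootstrap replicates for purity/reliability and changepoint quantiles.
    min_split : int, default 5
        Minimum samples per side of a split and minimum taxon occurrences.
    purity_min, reliability_min : float, default 0.95
        Bootstrap filters a taxon must pass to receive a trait and to join
        the community sum(z) profiles.
    select_by : {"z", "indval"}
        Changepoint selection statistic.
    n_boot_community : int or None
        Bootstrap replicates for the community changepoint cumulative
        frequency curves (None → ``n_boot``).
    random_state : int or None
        Master seed; per-taxon permutations/bootstraps use derived substreams.

    Attributes
    ----------
    results_ : list of TitanTaxonResult
    taxon_results_ : pandas.DataFrame (one row per analysed taxon)
    community_profile_ : CommunityZProfile
    trait_table_ : long-form trait rows, source "titan", for *all* taxa
    """

    def __init__(
        self,
        n_perm: int = 250,
        n_boot: int = 500,
        min_split: int = 5,
        purity_min: float = 0.95,
        reliability_min: float = 0.95,
        select_by: str = "z",
        n_boot_community: int | None = None,
        random_state=None,
    ):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.min_split = min_split
        self.purity_min = purity_min
        self.reliability_min = reliability_min
        self.select_by = select_by
        self.n_boot_community = n_boot_community
        self.random_state = random_state

    def fit(self, counts: pd.DataFrame, mat_p):
        x = np.asarray(mat_p, dtype=float)
        props = relative_abundance(counts)
        analyzable = counts.index[(counts > 0).sum(axis=1) >= self.min_split]
        self.results_ = []
        for i, taxon in enumerate(analyzable):
            y = props.loc[taxon].to_numpy()
            res = titan_taxon(
                y,
                x,
                n_perm=self.n_perm,
                min_split=self.min_split,
                seed=substream(self.random_state, "perm", i),
                select_by=self.select_by,
                taxon=str(taxon),
            )
            res.purity, res.reliability, res.cp_quantiles = titan_bootstrap(
                y,
                x,
                n_boot=self.n_boot,
                n_perm=self.n_perm,
                min_split=self.min_split,
                seed=substream(self.random_state, "taxonboot", i),
                direction=res.direction,
            )
            self.results_.append(res)
        rows = [
            {
                "taxon": r.taxon,
                "direction": r.direction,
                "changepoint": r.changepoint,
                "indval": r.indval,
                "z": r.z,
                "p": r.p,
                "purity": r.purity,
                "reliability": r.reliability,
                **{f"cp_q{int(q * 100):02d}": v for q, v in r.cp_quantiles.items()},
            }
            for r in self.results_
        ]
        self.taxon_results_ = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.community_profile_ = community_profile(
                self.results_, self.purity_min, self.reliability_min
            )
            self._community_bootstrap(props, x, analyzable)
        traits = traits_from_titan(
            self.taxon_results_, self.purity_min, self.reliability_min
        ) if len(self.taxon_results_) else pd.DataFrame(
            columns=["taxon", "source", "trait"]
        )
        # all taxa, unanalysed ones unassigned, plus WA columns for convenience
        wa = wa_table(counts, x)
        full = traits.set_index("taxon").reindex(counts.index)
        full["source"] = "titan"
        full["trait"] = full["trait"].fillna("unassigned")
        full["n_occurrences"] = (counts > 0).sum(axis=1)
        full["optimum"] = wa["optimum"]
        full["tolerance"] = wa["tolerance"]
        self.trait_table_ = full.reset_index(names="taxon")
        return self

    def _community_bootstrap(self, props: pd.DataFrame, x: np.ndarray, taxa):
        """Bootstrap the community changepoints into cumulative frequency curves."""
        n_boot = self.n_boot_community if self.n_boot_community is not None else self.n_boot
        passing = [
            r
            for r in self.results_
            if (np.isnan(r.purity) or r.purity >= self.purity_min)
            and (np.isnan(r.reliability) or r.reliability >= self.reliability_min)
        ]
        if not passing or n_boot == 0:
            return
        directions = {r.taxon: r.direction for r in passing}
        Y = props.loc[[r.taxon for r in passing]].to_numpy()
        n = len(x)
        cps = {"z-": [], "z+": []}
        for b in range(n_boot):
            rng = substream(self.random_state, "communityboot", b)
            idx = rng.integers(0, n, n)
            xs_order = np.argsort(x[idx], kind="stable")
            xs = x[idx][xs_order]
            ks = _candidates(xs, self.min_split)
            if len(ks) == 0:
                continue
            candidates = (xs[ks - 1] + xs[ks]) / 2.0
            sums = {"z-": np.zeros(len(ks)), "z+": np.zeros(len(ks))}
            for row, r in enumerate(passing):
                y = Y[row][idx][xs_order]
                if (y > 0).sum() < self.min_split:
                    continue
                iv_obs, _ = _indval_max_curves(y[None, :], ks)
                perms = rng.permuted(
                    np.broadcast_to(y, (self.n_perm, n)).copy(), axis=1
                )
                iv_perm, _ = _indval_max_curves(perms, ks)
                mu = iv_perm.mean(axis=0)
                sd = iv_perm.std(axis=0, ddof=1)
                z = np.where(sd > 0, (iv_obs[0] - mu) / np.where(sd > 0, sd, 1.0), 0.0)
                sums[directions[r.taxon]] += np.clip(z, 0.0, None)
            for d in ("z-", "z+"):
                if sums[d].any():
                    cps[d].append(float(candidates[int(np.argmax(sums[d]))]))
        prof = self.community_profile_
        for d, attr in (("z-", "boot_cum_minus"), ("z+", "boot_cum_plus")):
            if cps[d]:
                vals = pd.Series(sorted(cps[d]))
                cum = pd.Series(
                    np.arange(1, len(vals) + 1) / len(vals), index=vals.to_numpy()
                )
                setattr(prof, attr, cum)
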