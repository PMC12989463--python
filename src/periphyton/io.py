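"""Reading, validating and binding the three table kinds.

The package works with three plain-text tables:

* **count matrix** — integer diatom valve counts, taxa as rows and samples as
  columns (the microscopist's cross-tab);
* **sample table** — per-sample environment: mat P (total phosphorus of the
  periphyton mat, µg P g⁻¹ dry mass), region code, latitude/longitude, year,
  and optional water chemistry;
* **trait table** — per-taxon trait assignments (lowP / highP / unassigned)
  per source, with weighted-average optima and tolerances.

All are pandas DataFrames; this module adds validation and the
:class:`AnalysisSet` container that co-orders counts with their metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSet",
    "read_count_matrix",
    "read_sample_table",
    "read_trait_table",
    "validate_count_matrix",
    "validate_sample_table",
    "bind",
    "select_one_per_site",
    "write_table",
    "write_manifest",
]

SAMPLE_COLUMNS = ("mat_p", "region", "latitude", "longitude", "year")
TRAIT_COLUMNS = ("taxon", "source", "trait", "n_occurrences", "optimum", "tolerance")
TRAITS = ("lowP", "highP", "unassigned")
SOURCES = ("literature", "regression", "titan")


def _delimiter_for(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxa-by-samples valve count matrix, returning it unchanged.

    Counts must be non-negative integers, ids unique, and the matrix non-empty.
    Errors name the offending taxon/sample cell.
    """
    if counts.shape[0] < 1 or counts.shape[1] < 1:
        raise ValueError("count matrix needs at least 1 taxon and 1 sample")
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids: {dups}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric cells")
    bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"count for taxon {counts.index[i]!r} in sample {counts.columns[j]!r} "
            f"is {values[i, j]!r}; counts must be non-negative integers"
        )
    return counts.astype(np.int64)


def read_count_matrix(path, orientation: str = "taxa", delimiter=None) -> pd.DataFrame:
    """Read a delimited valve-count table and normalise to taxa-as-rows.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with an id header row and id first column.
    orientation : {"taxa", "samples"}
        Which entity the file's *rows* are. ``"samples"`` transposes.
    delimiter : str, optional
        Override the extension-based delimiter guess (.csv → ",", else tab).
    """
    if orientation not in ("taxa", "samples"):
        raise ValueError("orientation must be 'taxa' or 'samples'")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    if orientation == "samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_count_matrix(df)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table indexed by sample id."""
    if samples.index.duplicated().any():
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if "mat_p" in samples:
        mat_p = pd.to_numeric(samples["mat_p"], errors="coerce")
        bad = mat_p.notna() & (mat_p <= 0)
        if bad.any():
            raise ValueError(
                f"mat_p must be > 0 where present; offending samples: "
                f"{samples.index[bad].tolist()}"
            )
        samples = samples.assign(mat_p=mat_p)
    for col in ("latitude", "longitude"):
        if col in samples:
            vals = pd.to_numeric(samples[col], errors="coerce")
            bad = samples[col].notna() & ~np.isfinite(vals.fillna(np.inf))
            if bad.any():
                raise ValueError(f"non-finite {col} for {samples.index[bad].tolist()}")
            samples = samples.assign(**{col: vals})
    return samples


def read_sample_table(path, delimiter=None) -> pd.DataFrame:
    """Read per-sample metadata (first column = sample id). "NA"/empty = missing."""
    df = pd.read_csv(
        path, sep=_delimiter_for(path, delimiter), index_col=0,
        na_values=["NA", "na", ""],
    )
    df.index = df.index.astype(str)
    return validate_sample_table(df)


def read_trait_table(path, delimiter=None) -> pd.DataFrame:
    """Read a long-form trait table (one row per taxon × source)."""
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), na_values=["NA", ""])
    missing = set(("taxon", "source", "trait")) - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if df.duplicated(["taxon", "source"]).any():
        raise ValueError("duplicate (taxon, source) rows in trait table")
    bad = ~df["trait"].isin(TRAITS)
    if bad.any():
        raise ValueError(f"unknown trait values: {df.loc[bad, 'trait'].unique().tolist()}")
    return df


@dataclass
class AnalysisSet:
    """Valve counts bound to co-ordered sample metadata.

    ``samples`` is restricted to, and ordered like, the columns of ``counts``.
    Samples lacking mat P are retained but flagged; gradient-dependent
    operations should subset with :meth:`with_gradient`.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    missing_mat_p: list = field(default_factory=list)

    def with_gradient(self) -> "AnalysisSet":
        """Return the subset of samples that have a mat P measurement."""
        keep = self.samples["mat_p"].notna()
        return AnalysisSet(
            self.counts.loc[:, keep.to_numpy()], self.samples.loc[keep], []
        )

    @property
    def mat_p(self) -> pd.Series:
        return self.samples["mat_p"]


def bind(counts: pd.DataFrame, samples: pd.DataFrame) -> AnalysisSet:
    """Bind a count matrix to its metadata into one co-ordered AnalysisSet."""
    counts = validate_count_matrix(counts)
    samples = validate_sample_table(samples)
    unmatched = [s for s in counts.columns if s not in samples.index]
    if unmatched:
        raise ValueError(f"count samples missing from sample table: {unmatched}")
    samples = samples.loc[list(counts.columns)]
    if "mat_p" in samples:
        missing = samples.index[samples["mat_p"].isna()].tolist()
    else:
        missing = samples.index.tolist()
    if missing:
        logger.info("%d sample(s) lack mat P: %s", len(missing), missing)
    return AnalysisSet(counts, samples, missing)


def select_one_per_site(sample_ids, site_of, seed=None) -> list:
    """Randomly select exactly one sample per site, reproducibly.

    Parameters
    ----------
    sample_ids : sequence of sample ids
    site_of : mapping sample id → site id
    seed : int, Generator or None
    """
    rng = as_rng(seed)
    by_site: dict = {}
    for s in sample_ids:
        if s not in site_of:
            warnings.warn(f"sample {s!r} has no site; skipped")
            continue
        by_site.setdefault(site_of[s], []).append(s)
    chosen = []
    for site in sorted(by_site, key=str):
        members = sorted(by_site[site], key=str)
        chosen.append(members[rng.integers(len(members))])
    return chosen


def write_table(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep=_delimiter_for(path), index=index)


def write_manifest(path, *, seed=None, parameters=None, inputs=()) -> dict:
    """Write a JSON run manifest (version, parameters, seed, input digests)."""
    from . import __version__

    digests = {}
    for p in inputs:
        p = Path(p)
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "tool": "periphyton",
        "version": __version__,
        "seed": seed,
        "parameters": parameters or {},
        "input_sha256": digests,
        "timestamp": pd.Timestamp.now(tz="UTC").isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
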