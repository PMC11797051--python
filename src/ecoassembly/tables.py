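"""ASV/zOTU count tables: I/O, quality filtering and depth normalization.

The central container is :class:`CountTable`, an integer taxa x samples
matrix with optional taxonomy labels. Filters implement the usual amplicon
QC steps: removal of low-abundance taxa, exclusion of taxa observed in
negative controls (with an escape hatch for abundant taxa that picked up
trace reads in the controls), a curated drop-list for known artefacts such
as host-gene amplicons, and total-sum scaling of every sample to a common
read depth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SAMPLE_TYPES",
    "METADATA_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "filter_min_reads",
    "subtract_control_asvs",
    "drop_taxa",
    "normalize_scaling",
]

SAMPLE_TYPES = ("gut", "rearing_water", "added_water", "negative_control")
METADATA_COLUMNS = (
    "sample_id",
    "sample_type",
    "water_treatment",
    "strain",
    "flask_id",
    "day_dph",
)


class CountTableError(ValueError):
    """Raised for malformed count tables or metadata."""


@dataclass(frozen=True)
class CountTable:
    """Integer taxa x samples count matrix.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample id.
        All entries must be nonnegative integers.
    taxonomy
        Optional per-taxon lineage strings, carried through filters but
        never computed.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate taxon ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise CountTableError("counts must be numeric")
            if np.any(arr < 0):
                t, s = np.argwhere(arr < 0)[0]
                raise CountTableError(
                    f"negative count at taxon {counts.index[t]!r}, "
                    f"sample {counts.columns[s]!r}"
                )
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                t, s = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise CountTableError(
                    f"non-integer count at taxon {counts.index[t]!r}, "
                    f"sample {counts.columns[s]!r}"
                )
        if not np.issubdtype(arr.dtype, np.integer):
            object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.taxonomy is not None and not self.taxonomy.index.equals(counts.index):
            raise CountTableError("taxonomy index must match taxon ids")

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise CountTableError(f"all-zero samples: {bad}")
        return self.counts / totals

    def select_taxa(self, taxon_ids: Sequence) -> "CountTable":
        tax = None if self.taxonomy is None else self.taxonomy.loc[list(taxon_ids)]
        return CountTable(self.counts.loc[list(taxon_ids)], tax)

    def select_samples(self, sample_ids: Sequence) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)], self.taxonomy)


# ---------------------------------------------------------------------------
# I/O: tab-separated taxa x samples with a header row of sample ids.
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path | io.StringIO) -> CountTable:
    """Read a tab-separated taxa x samples table (first column: taxon ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise CountTableError("no taxa in table")
    if raw.shape[1] == 0:
        raise CountTableError("no samples in table")
    data = {}
    for col in raw.columns:
        try:
            vals = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()][0]
            raise CountTableError(
                f"non-numeric count at taxon {bad!r}, sample {col!r}"
            ) from None
        data[col] = vals
    df = pd.DataFrame(data, index=raw.index)
    df.index.name = raw.index.name or "taxon_id"
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = df.index.name or "taxon_id"
    df.to_csv(path, sep="\t")


def validate_metadata(metadata: pd.DataFrame, table: CountTable | None = None) -> pd.DataFrame:
    """Check a metadata frame against the expected schema.

    Returns the frame indexed by ``sample_id``. If ``table`` is given, every
    sample in the table must have exactly one metadata row.
    """
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    if md.index.has_duplicates:
        dups = md.index[md.index.duplicated()].unique().tolist()
        raise CountTableError(f"duplicate metadata sample ids: {dups}")
    missing_cols = {"sample_type"} - set(md.columns)
    if missing_cols:
        raise CountTableError(f"metadata missing columns: {sorted(missing_cols)}")
    bad_types = set(md["sample_type"]) - set(SAMPLE_TYPES)
    if bad_types:
        raise CountTableError(f"unknown sample_type values: {sorted(bad_types)}")
    if table is not None:
        missing = set(table.sample_ids) - set(md.index)
        if missing:
            raise CountTableError(f"samples without metadata: {sorted(missing)}")
    return md


def read_metadata(path: str | Path | io.StringIO) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "flask_id": str})
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    md = metadata.reset_index() if metadata.index.name == "sample_id" else metadata
    md.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_min_reads(
    table: CountTable, threshold: int = 8, mode: str = "total"
) -> CountTable:
    """Remove taxa with too few reads.

    mode="total": drop taxa whose summed count across all samples is below
    ``threshold`` (the USEARCH-style total-abundance filter).
    mode="per_sample_max": drop taxa whose largest single-sample count is
    below ``threshold`` (stricter reading of "fewer than t reads in all
    samples").
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode == "total":
        keep = table.counts.sum(axis=1) >= threshold
    elif mode == "per_sample_max":
        keep = table.counts.max(axis=1) >= threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return table.select_taxa(table.counts.index[keep])


def subtract_control_asvs(
    table: CountTable,
    control_sample_ids: Iterable,
    control_read_cap: int = 4,
    abundance_floor: float = 0.001,
) -> CountTable:
    """Exclude taxa observed in negative controls, with an abundance exception.

    A taxon with any reads in the control samples is removed unless its
    summed control reads are below ``control_read_cap`` AND its mean relative
    abundance across the biological (non-control) samples is at least
    ``abundance_floor`` — i.e. abundant community members that picked up
    trace contamination in the controls are retained. Control samples are
    dropped from the output.
    """
    controls = list(control_sample_ids)
    unknown = set(controls) - set(table.sample_ids)
    if unknown:
        raise CountTableError(f"unknown control sample ids: {sorted(unknown)}")
    bio = [s for s in table.sample_ids if s not in set(controls)]
    if not bio:
        raise CountTableError("no biological samples left after removing controls")

    ctrl_sum = table.counts[controls].sum(axis=1)
    bio_counts = table.counts[bio]
    totals = bio_counts.sum(axis=0)
    # all-zero biological samples contribute zero abundance, not NaN
    rel = bio_counts.div(totals.replace(0, 1), axis=1)
    mean_rel = rel.mean(axis=1)

    observed_in_controls = ctrl_sum > 0
    exception = (ctrl_sum < control_read_cap) & (mean_rel >= abundance_floor)
    keep = ~observed_in_controls | exception
    return table.select_taxa(table.counts.index[keep]).select_samples(bio)


def drop_taxa(table: CountTable, taxon_ids: Iterable) -> CountTable:
    """Remove a curated list of taxa (e.g. host-gene ASVs) by id."""
    drop = set(taxon_ids)
    unknown = drop - set(table.taxon_ids)
    if unknown:
        raise CountTableError(f"drop-list ids not in table: {sorted(unknown)}")
    keep = [t for t in table.taxon_ids if t not in drop]
    return table.select_taxa(keep)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def normalize_scaling(
    table: CountTable, depth: int = 11000, rounding: str = "half_up"
) -> CountTable:
    """Scale every sample to a common read depth.

    Each count becomes ``round(count / sample_total * depth)``. Column sums
    are not repaired afterwards; they can deviate from ``depth`` by at most
    ``ceil(n_taxa / 2)`` under half-up rounding.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise CountTableError(f"cannot normalize all-zero samples: {bad}")
    frac = table.counts.to_numpy(dtype=float) / totals.to_numpy(dtype=float)
    scaled = frac * depth
    if rounding == "half_up":
        out = _round_half_up(scaled)
    elif rounding == "banker":
        out = np.rint(scaled)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    df = pd.DataFrame(
        out.astype(np.int64), index=table.counts.index, columns=table.counts.columns
    )
    return CountTable(df, table.taxonomy)
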