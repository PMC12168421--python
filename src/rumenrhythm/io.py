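"""Readers and writers for the plain-TSV interchange formats.

All tables are tab-separated text with an optional leading ``#`` comment line
carrying column units, which keeps files diff-friendly and round-trippable to
full float precision.  The canonical tables are:

* abundance: first column ``sample_id``, remaining columns taxon ids;
  fractions mode requires each row to sum to 1 (within 1e-6).
* metadata: sample_id, cow_id, group, clock_time, after_feeding_h, day.
* qpcr: sample_id, kingdom, total_copies_per_ml (plus optional raw columns).
* fermentation: sample_id plus the six VFA columns (mM), ph, nh3n.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "GROUPS",
    "SampleMetadata",
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_tsv",
    "write_tsv",
]

GROUPS = ("ALF", "DF", "NF", "RFT2d", "RFT7d")

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's provenance within the study design."""

    sample_id: str
    cow_id: str
    group: str
    clock_time: float
    after_feeding_h: float
    day: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not (0.0 <= self.clock_time < 24.0):
            raise FormatError(f"clock_time {self.clock_time} outside [0, 24)")


class AbundanceTable:
    """Samples-by-taxa table of relative abundances (fractions) or counts."""

    def __init__(self, data: pd.DataFrame, mode: str = "fractions"):
        if mode not in ("fractions", "counts"):
            raise FormatError(f"mode must be 'fractions' or 'counts', got {mode!r}")
        if data.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if data.columns.has_duplicates:
            raise FormatError("duplicate taxon ids")
        vals = data.to_numpy(dtype=float)
        if np.any(vals < 0):
            bad = data.index[np.any(vals < 0, axis=1)][0]
            raise FormatError(f"negative abundance in row {bad!r}")
        if mode == "fractions":
            sums = vals.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-6
            if np.any(off):
                bad = data.index[off][0]
                raise FormatError(f"row {bad!r} sums to {sums[off][0]:.6g}, expected 1")
        self.data = data
        self.mode = mode

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    def to_fractions(self) -> "AbundanceTable":
        if self.mode == "fractions":
            return self
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise FormatError(f"row {bad!r} sums to 0 and cannot be normalized")
        return AbundanceTable(self.data.div(sums, axis=0), mode="fractions")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceTable)
            and self.mode == other.mode
            and self.data.equals(other.data)
        )


def read_abundance_table(path, mode: str = "fractions") -> AbundanceTable:
    """Read an abundance TSV (header row of taxon ids, first column sample_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return AbundanceTable(df, mode=mode)


def write_abundance_table(table: AbundanceTable, path) -> None:
    path = Path(path)
    unit = "fraction of sample total" if table.mode == "fractions" else "read counts"
    with open(path, "w") as fh:
        fh.write(f"# sample_id x taxon_id; values: {unit}\n")
        table.data.to_csv(fh, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "cow_id", "group", "clock_time", "after_feeding_h", "day"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    df = df.astype({"clock_time": float, "after_feeding_h": float, "day": int})
    # Validate each record through the dataclass.
    for rec in df.itertuples(index=False):
        SampleMetadata(
            sample_id=str(rec.sample_id),
            cow_id=str(rec.cow_id),
            group=str(rec.group),
            clock_time=float(rec.clock_time),
            after_feeding_h=float(rec.after_feeding_h),
            day=int(rec.day),
        )
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# clock_time, after_feeding_h: hours; day: index from 1\n")
        metadata.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tsv(path) -> pd.DataFrame:
    """Generic TSV reader honouring '#' comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path, units: str | None = None, index: bool = False) -> None:
    """Generic TSV writer with an optional '#' units comment line."""
    with open(path, "w") as fh:
        if units:
            fh.write(f"# {units}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT)
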