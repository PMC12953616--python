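"""Barcode count tables.

A :class:`CountTable` holds integer read counts (or RPM-normalized values)
for a set of barcodes across samples. Technical replicates are encoded in the
column names as ``<sample>_rep<k>``; a column without the suffix is treated as
a single-replicate sample. Tables round-trip through TSV with a leading
``barcode`` column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountTable", "RPM_SCALE"]

RPM_SCALE = 1_000_000
_REP_RE = re.compile(r"^(?P<sample>.+)_rep(?P<rep>\d+)$")


@dataclass
class CountTable:
    """Barcodes x samples table of read counts.

    Parameters
    ----------
    data
        DataFrame indexed by barcode id, one column per sample/replicate.
    units
        ``"reads"`` for raw integer counts, ``"rpm"`` for reads-per-million.
    """

    data: pd.DataFrame
    units: str = "reads"

    def __post_init__(self) -> None:
        if self.units not in ("reads", "rpm"):
            raise ValueError(f"units must be 'reads' or 'rpm', got {self.units!r}")
        if not self.data.index.is_unique:
            raise ValueError("barcode ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    # -- structure ---------------------------------------------------------

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map sample name -> its replicate columns (insertion order)."""
        groups: dict[str, list[str]] = {}
        for col in self.data.columns:
            m = _REP_RE.match(col)
            name = m.group("sample") if m else col
            groups.setdefault(name, []).append(col)
        return groups

    def depths(self) -> pd.Series:
        return self.data.sum(axis=0)

    # -- normalization -----------------------------------------------------

    def to_rpm(self) -> "CountTable":
        """Scale every column to sum to one million."""
        if self.units == "rpm":
            return CountTable(self.data.copy(), units="rpm")
        depths = self.depths()
        if (depths <= 0).any():
            bad = list(depths.index[depths <= 0])
            raise ValueError(f"zero-depth column(s): {bad}")
        return CountTable(self.data / depths * RPM_SCALE, units="rpm")

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "barcode"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, units: str = "reads") -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if "barcode" not in df.columns:
            raise ValueError(f"{path}: missing 'barcode' column")
        df = df.set_index("barcode")
        if df.shape[1] == 0:
            raise ValueError(f"{path}: no sample columns")
        values = df.apply(pd.to_numeric, errors="coerce")
        if values.isna().any().any():
            raise ValueError(f"{path}: non-numeric count values")
        return cls(values, units=units)

    def column_counts(self, column: str) -> pd.Series:
        if column not in self.data.columns:
            raise KeyError(column)
        return self.data[column]
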