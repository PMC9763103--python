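"""Marker map: biallelic SNV positions in physical (bp) and genetic (cM) units.

Coordinates are 1-based inclusive with GRCh38-style chromosome naming.
Interval length throughout the package is ``end_bp - start_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "pos_bp", "pos_cm", "ref", "alt", "id"]


@dataclass
class MarkerMap:
    """Table of biallelic markers, sorted by chromosome then position.

    The underlying table has columns ``chrom`` (str), ``pos_bp`` (int,
    1-based), ``pos_cm`` (float), ``ref``/``alt`` (single characters) and
    ``id`` (rsID or synthetic identifier).  Positions must be strictly
    increasing within each chromosome in both bp and cM.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker table missing columns {missing}")
        self.table = self.table[_COLUMNS].reset_index(drop=True)
        self.table["pos_bp"] = self.table["pos_bp"].astype(np.int64)
        self.table["pos_cm"] = self.table["pos_cm"].astype(float)
        for _, sub in self.table.groupby("chrom", sort=False):
            if not (np.diff(sub["pos_bp"].to_numpy()) > 0).all():
                raise ValueError("marker bp positions not strictly increasing")
            if not (np.diff(sub["pos_cm"].to_numpy()) > 0).all():
                raise ValueError("marker cM positions not strictly increasing")
        bad = (self.table["ref"].str.len() != 1) | (self.table["alt"].str.len() != 1)
        if bad.any():
            raise ValueError("markers must be biallelic SNVs with single-character alleles")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def pos_cm(self) -> np.ndarray:
        return self.table["pos_cm"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Row indices of all markers on *chrom*."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def interval_indices(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Row indices of markers within [start_bp, end_bp] on *chrom*."""
        idx = self.chrom_indices(chrom)
        pos = self.pos_bp[idx]
        return idx[(pos >= start_bp) & (pos <= end_bp)]

    def subset(self, indices) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(indices)].reset_index(drop=True))

    def index_of_ids(self, ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.table["id"])}
        return np.array([lookup[i] for i in ids], dtype=np.int64)
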