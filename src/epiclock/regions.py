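"""Genomic interval sets (BED convention: 0-based, half-open).

CpG positions elsewhere in the package are 1-based; a site at 1-based
position ``p`` falls in region ``[start, end)`` iff ``start <= p - 1 < end``.
The conversion happens here, at the boundary, and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["RegionSet", "read_bed", "write_bed"]


@dataclass
class RegionSet:
    """An ordered list of (chrom, start, end[, name]) intervals."""

    regions: pd.DataFrame  # columns: chrom, start, end, name
    label: str = "regions"
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.regions.reset_index(drop=True).copy()
        if "name" not in df.columns:
            df["name"] = [f"{self.label}_{i}" for i in range(len(df))]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"region with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.regions = df[["chrom", "start", "end", "name"]]

    def __len__(self) -> int:
        return len(self.regions)

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            sub = self.regions[self.regions["chrom"] == chrom]
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), int(i)) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
            )
        return self._trees[chrom]

    def overlapping(self, chrom: str, pos_1based: int) -> list[int]:
        """Indices (row order) of regions containing a 1-based position."""
        return sorted(iv.data for iv in self._tree(chrom)[pos_1based - 1])

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return bool(self._tree(chrom)[pos_1based - 1])

    def near(self, chrom: str, pos_1based: int, max_dist: int) -> list[int]:
        """Indices of regions within ``max_dist`` bp of a 1-based position."""
        p = pos_1based - 1
        return sorted(iv.data for iv in self._tree(chrom)[p - max_dist:p + max_dist + 1])

    def subset(self, indices: Sequence[int], label: str | None = None) -> "RegionSet":
        return RegionSet(self.regions.iloc[list(indices)], label or self.label)

    @staticmethod
    def from_tuples(tuples: Sequence[tuple], label: str = "regions") -> "RegionSet":
        cols = ["chrom", "start", "end", "name"][: len(tuples[0])] if tuples else ["chrom", "start", "end"]
        return RegionSet(pd.DataFrame(list(tuples), columns=cols), label)


def read_bed(path: str | Path, label: str | None = None) -> RegionSet:
    """Read a BED3/BED4+ file (0-based, half-open) into a RegionSet."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                     dtype={0: str}, on_bad_lines="error") \
        if _n_cols(path) >= 4 else \
        pd.read_csv(path, sep="\t", header=None, comment="#",
                    names=["chrom", "start", "end"], dtype={0: str})
    return RegionSet(df, label or path.stem)


def _n_cols(path: Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 3


def write_bed(rs: RegionSet, path: str | Path) -> None:
    rs.regions.to_csv(path, sep="\t", header=False, index=False)
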