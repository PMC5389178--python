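"""Bismark coverage I/O and the cross-sample methylation matrix.

RRBS pipelines emit one Bismark ``.cov`` file per sample: tab-separated
records of chromosome, 1-based position (start == end per CpG), methylation
percentage, methylated read count and unmethylated read count.  This module
parses those files, assembles them into a sites x samples count matrix, and
reads the accompanying sample metadata sheet (sample id, age, tissue, ...).

Conventions
-----------
* Coverage positions are kept 1-based throughout the package; BED inputs
  (handled in :mod:`epiclock.region_clock` / :mod:`epiclock.genomic_context`)
  are 0-based half-open and converted at the boundary.
* Counts are the source of truth; the percentage column is checked for
  consistency but never used in computation.
* Files ending in ``.gz`` are decompressed transparently.
* Chromosome names are normalised to a configurable convention
  (default: ensure a ``chr`` prefix) so multi-dataset dialects merge cleanly.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "MethylationMatrix",
    "SampleMeta",
    "CoverageParseError",
    "read_bismark_cov",
    "write_bismark_cov",
    "merge_samples",
    "read_metadata",
    "write_metadata",
    "normalize_chrom",
]


class CoverageParseError(ValueError):
    """Malformed Bismark coverage record (reports file and line number)."""


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single CpG position (1-based)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


def normalize_chrom(chrom: str, convention: Literal["chr", "plain", "none"] = "chr") -> str:
    """Reconcile chromosome-name dialects ('1' vs 'chr1').

    ``chr`` enforces a ``chr`` prefix, ``plain`` strips it, ``none`` leaves
    names untouched.
    """
    if convention == "none":
        return chrom
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if convention == "chr" else bare


def _site_index(sites: Iterable[CpGSite]) -> pd.MultiIndex:
    tuples = [(s.chrom, s.pos) for s in sites]
    return pd.MultiIndex.from_tuples(tuples, names=["chrom", "pos"]) if tuples else \
        pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])


@dataclass
class MethylationMatrix:
    """Sites x samples methylated / total read counts.

    ``meth`` and ``total`` are integer DataFrames indexed by (chrom, pos)
    with one column per sample.  A cell with ``total == 0`` is missing;
    ``fraction`` is NaN there and ``meth/total`` elsewhere.  Site order is
    deterministic: (chrom, pos) ascending.
    """

    meth: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.total.index) or not list(self.meth.columns) == list(self.total.columns):
            raise ValueError("meth and total must share index and columns")
        if self.meth.index.has_duplicates:
            raise ValueError("duplicate (chrom, pos) sites")
        if ((self.total.to_numpy() < 0) | (self.meth.to_numpy() < 0)).any():
            raise ValueError("negative counts")
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("meth_count exceeds total_count")
        order = self.meth.index.sortlevel(["chrom", "pos"])[0]
        if not order.equals(self.meth.index):
            self.meth = self.meth.loc[order]
            self.total = self.total.loc[order]

    # -- accessors -------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def sites(self) -> list[CpGSite]:
        return [CpGSite(c, int(p)) for c, p in self.meth.index]

    @property
    def n_sites(self) -> int:
        return self.meth.shape[0]

    @property
    def fraction(self) -> pd.DataFrame:
        """Methylated fraction per cell; NaN where total == 0."""
        total = self.total.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, self.meth.to_numpy(dtype=float) / total, np.nan)
        return pd.DataFrame(frac, index=self.meth.index, columns=self.meth.columns)

    def subset_sites(self, index: pd.MultiIndex | Sequence[CpGSite]) -> "MethylationMatrix":
        if not isinstance(index, pd.MultiIndex):
            index = _site_index(index)
        return MethylationMatrix(self.meth.loc[index], self.total.loc[index])

    def subset_samples(self, samples: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.meth[list(samples)], self.total[list(samples)])

    @staticmethod
    def from_records(sites: Sequence[CpGSite], samples: Sequence[str],
                     meth: np.ndarray, total: np.ndarray) -> "MethylationMatrix":
        idx = _site_index(sites)
        return MethylationMatrix(
            pd.DataFrame(np.asarray(meth, dtype=np.int64), index=idx, columns=list(samples)),
            pd.DataFrame(np.asarray(total, dtype=np.int64), index=idx, columns=list(samples)),
        )


@dataclass
class SampleMeta:
    """Per-sample phenotype record."""

    sample_id: str
    age_weeks: float
    age_days: int | None = None
    tissue: str = "unknown"
    sex: str = "unknown"
    dataset: str = "unknown"
    treatment: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_weeks < 0:
            raise ValueError(f"negative age for sample {self.sample_id!r}")
        derived = int(round(7 * self.age_weeks))
        if self.age_days is None:
            self.age_days = derived
        elif self.age_days != derived:
            raise ValueError(
                f"age_days={self.age_days} inconsistent with age_weeks={self.age_weeks} "
                f"for sample {self.sample_id!r}"
            )


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_bismark_cov(path: str | Path, sample_id: str, *,
                     chrom_convention: Literal["chr", "plain", "none"] = "chr",
                     check_percentage: bool = True) -> MethylationMatrix:
    """Read one Bismark coverage file into a single-sample matrix.

    Each line: chrom, start (1-based), end, methylation %, count methylated,
    count unmethylated.  Fractions are recomputed from the counts; a
    percentage deviating from them by more than one point raises a warning.
    """
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    totals: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CoverageParseError(f"{path}:{lineno}: expected >= 6 fields, got {len(fields)}")
            chrom, start, _end, pct, n_meth, n_unmeth = fields[:6]
            try:
                pos = int(start)
                m = int(n_meth)
                u = int(n_unmeth)
                pct_val = float(pct)
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if m < 0 or u < 0:
                raise CoverageParseError(f"{path}:{lineno}: negative count")
            if m + u == 0:
                raise CoverageParseError(f"{path}:{lineno}: zero total count")
            if pos < 1:
                raise CoverageParseError(f"{path}:{lineno}: position must be 1-based positive")
            if check_percentage and abs(pct_val / 100.0 - m / (m + u)) > 0.01:
                warnings.warn(
                    f"{path}:{lineno}: percentage column ({pct_val}) disagrees with counts "
                    f"({m}/{m + u}); counts used",
                    stacklevel=2,
                )
            chroms.append(normalize_chrom(chrom, chrom_convention))
            poss.append(pos)
            meths.append(m)
            totals.append(m + u)

    idx = pd.MultiIndex.from_arrays([chroms, poss], names=["chrom", "pos"]) if chroms else \
        pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise CoverageParseError(f"{path}: duplicate site {dup}")
    return MethylationMatrix(
        pd.DataFrame({sample_id: pd.array(meths, dtype=np.int64)}, index=idx),
        pd.DataFrame({sample_id: pd.array(totals, dtype=np.int64)}, index=idx),
    )


def write_bismark_cov(matrix: MethylationMatrix, path: str | Path, sample: str | None = None) -> None:
    """Write one sample of a matrix as a Bismark coverage file.

    Cells with zero total coverage are omitted (a coverage file only lists
    observed CpGs), so ``read_bismark_cov(write(...))`` round-trips counts
    exactly.
    """
    if sample is None:
        if len(matrix.samples) != 1:
            raise ValueError("matrix has several samples; pass `sample`")
        sample = matrix.samples[0]
    meth = matrix.meth[sample].to_numpy()
    total = matrix.total[sample].to_numpy()
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for (chrom, pos), m, t in zip(matrix.meth.index, meth, total):
            if t == 0:
                continue
            pct = 100.0 * m / t
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:g}\t{m}\t{t - m}\n")


def merge_samples(matrices: Sequence[MethylationMatrix],
                  mode: Literal["union", "intersection"] = "union") -> MethylationMatrix:
    """Combine single-sample (or multi-sample) matrices over a common site set.

    ``union`` keeps every site, filling uncovered cells with zero total
    (missing); ``intersection`` keeps only sites covered (total > 0) in every
    sample of every input.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.samples)
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample ids across matrices")

    meth = pd.concat([m.meth for m in matrices], axis=1)
    total = pd.concat([m.total for m in matrices], axis=1)
    meth = meth.fillna(0).astype(np.int64)
    total = total.fillna(0).astype(np.int64)
    merged = MethylationMatrix(meth, total)
    if mode == "intersection":
        keep = (merged.total.to_numpy() > 0).all(axis=1)
        merged = MethylationMatrix(merged.meth.loc[keep], merged.total.loc[keep])
    elif mode != "union":
        raise ValueError(f"unknown mode {mode!r}")
    return merged


_AGE_COLS = ("age_weeks", "age", "age_wk")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet (TSV or CSV with header).

    Requires ``sample_id`` and an age column (weeks); ``age_days`` is derived
    when absent.  Unknown columns are preserved in ``SampleMeta.extra``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    age_col = next((c for c in _AGE_COLS if c in df.columns), None)
    if age_col is None:
        raise ValueError(f"{path}: missing age column (one of {_AGE_COLS})")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")

    known = {"sample_id", age_col, "age_days", "tissue", "sex", "dataset", "treatment"}
    out = []
    for _, row in df.iterrows():
        age_weeks = float(row[age_col])
        treatment = row.get("treatment")
        if pd.isna(treatment):
            treatment = None
        out.append(SampleMeta(
            sample_id=str(row["sample_id"]),
            age_weeks=age_weeks,
            age_days=int(row["age_days"]) if "age_days" in df.columns and pd.notna(row.get("age_days")) else None,
            tissue=str(row["tissue"]) if pd.notna(row.get("tissue")) else "unknown",
            sex=str(row["sex"]) if pd.notna(row.get("sex")) else "unknown",
            dataset=str(row["dataset"]) if pd.notna(row.get("dataset")) else "unknown",
            treatment=None if treatment is None else str(treatment),
            extra={c: row[c] for c in df.columns if c not in known},
        ))
    return out


def write_metadata(meta: Sequence[SampleMeta], path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = [{
        "sample_id": m.sample_id, "age_weeks": m.age_weeks, "age_days": m.age_days,
        "tissue": m.tissue, "sex": m.sex, "dataset": m.dataset,
        "treatment": "" if m.treatment is None else m.treatment, **m.extra,
    } for m in meta]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
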