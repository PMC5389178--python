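"""Training the multi-tissue methylation clock.

Pipeline: intersect CpG sites usable (>= 5 reads) in every sample, drop sex
chromosomes and the mitochondrial genome, quantile-normalize methylation
fractions across samples, z-score per site, fit an elastic net predicting
log(age_weeks + 3) with a double-loop cross-validation over the mixing
parameter alpha and penalty lambda, and finally fit a quadratic calibration
mapping the raw summed beta score x = sum_i beta_i z_i to log age.  The
3-week offset lets the clock express pre-birth ages; predicted age is
exp(a x^2 + b x + c) - 3 weeks.

The serialized model carries everything prediction needs: selected sites
and weights, the training reference distribution for single-sample
quantile mapping, per-site means/sds on that mapped scale, the calibration
coefficients and the age offset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _linear
from ._linear import (CVReport, double_loop_cv, fit_quadratic,  # noqa: F401 (re-exported)
                      map_sample_to_reference, quantile_normalize, standardize)
from .io_rrbs import CpGSite, MethylationMatrix, SampleMeta, normalize_chrom

__all__ = [
    "ClockModel",
    "intersect_usable_sites",
    "quantile_normalize",
    "standardize",
    "transform_age",
    "inverse_transform_age",
    "train_elastic_net",
    "fit_calibration",
    "train_clock",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
_EXCLUDED_CHROMS = {"chrX", "chrY", "chrM", "chrMT"}


def _excluded(chrom: str) -> bool:
    return normalize_chrom(chrom, "chr") in _EXCLUDED_CHROMS


def intersect_usable_sites(matrices: Sequence[MethylationMatrix],
                           min_cov: int = 5) -> pd.MultiIndex:
    """Sites covered >= ``min_cov`` in every sample of every matrix.

    Sex chromosomes (X, Y) and the mitochondrial genome are excluded so the
    model is neither sex-specific nor exposed to the unreliable
    mitochondrial bisulfite signal.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    idx = None
    per_sample_pass: dict[str, int] = {}
    for m in matrices:
        ok = m.total.to_numpy() >= min_cov
        for j, s in enumerate(m.samples):
            per_sample_pass[s] = int(ok[:, j].sum())
        mask = ok.all(axis=1)
        this = m.meth.index[mask]
        idx = this if idx is None else idx.intersection(this)
    keep = [not _excluded(c) for c, _ in idx]
    idx = idx[keep]
    if len(idx) == 0:
        worst = min(per_sample_pass, key=per_sample_pass.get)
        raise ValueError(
            f"no site reaches {min_cov}x in all samples; most restrictive sample: "
            f"{worst!r} with {per_sample_pass[worst]} usable sites"
        )
    return idx.sortlevel(["chrom", "pos"])[0]


def transform_age(age_weeks: float | np.ndarray, offset: float = 3.0) -> float | np.ndarray:
    """log(age_weeks + offset); the offset admits pre-birth samples."""
    age = np.asarray(age_weeks, dtype=float)
    if np.any(age + offset <= 0):
        raise ValueError(f"age_weeks must exceed -{offset}")
    out = np.log(age + offset)
    return float(out) if out.ndim == 0 else out


def inverse_transform_age(log_age: float | np.ndarray, offset: float = 3.0) -> float | np.ndarray:
    out = np.exp(np.asarray(log_age, dtype=float)) - offset
    return float(out) if out.ndim == 0 else out


def train_elastic_net(z_matrix: pd.DataFrame, log_ages: np.ndarray,
                      alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                      n_folds: int = 10, seed: int = 0, *,
                      outer_folds: int = 10, strata=None) -> tuple[np.ndarray, float, float, CVReport]:
    """Double-loop CV elastic net on a standardized sites x samples matrix.

    Inner folds choose (alpha, lambda) by CV mean squared error over the
    alpha grid and an automatic lambda path; outer folds report held-out
    MSE; the returned weights are refit on all samples at the selection.
    """
    X = z_matrix.to_numpy(dtype=float).T  # samples x sites
    y = np.asarray(log_ages, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("log_ages length must match the number of samples")
    w, report = double_loop_cv(X, y, alpha_grid, inner_folds=n_folds,
                               outer_folds=outer_folds, seed=seed, strata=strata)
    return w, report.alpha, report.lam, report


fit_calibration = fit_quadratic


@dataclass
class ClockModel:
    """A trained methylation clock, serializable to versioned JSON."""

    sites: list[CpGSite]
    weights: np.ndarray
    reference_quantiles: np.ndarray
    site_means: np.ndarray
    site_sds: np.ndarray
    calibration: tuple[float, float, float]  # (a, b, c): log_age = a x^2 + b x + c
    age_offset_weeks: float = 3.0
    alpha: float | None = None
    lam: float | None = None
    training_info: dict = field(default_factory=dict)

    FORMAT_VERSION = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.reference_quantiles = np.sort(np.asarray(self.reference_quantiles, dtype=float))
        self.site_means = np.asarray(self.site_means, dtype=float)
        self.site_sds = np.asarray(self.site_sds, dtype=float)
        k = len(self.sites)
        if not (len(self.weights) == len(self.site_means) == len(self.site_sds) == k):
            raise ValueError("sites, weights, means and sds must have equal length")
        if np.any(self.site_sds <= 0):
            raise ValueError("all site_sds must be positive")
        bad = [s for s in self.sites if _excluded(s.chrom)]
        if bad:
            raise ValueError(f"model contains sex/mitochondrial sites, e.g. {bad[0]}")
        if len({(s.chrom, s.pos) for s in self.sites}) != k:
            raise ValueError("duplicate sites in model")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def calibrate(self, x: float) -> float:
        a, b, c = self.calibration
        return a * x * x + b * x + c

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format_version": self.FORMAT_VERSION,
            "model": "methylation-age-clock",
            "sites": [[s.chrom, s.pos] for s in self.sites],
            "weights": self.weights.tolist(),
            "reference_quantiles": self.reference_quantiles.tolist(),
            "site_means": self.site_means.tolist(),
            "site_sds": self.site_sds.tolist(),
            "calibration": list(self.calibration),
            "age_offset_weeks": self.age_offset_weeks,
            "alpha": self.alpha,
            "lambda": self.lam,
            "training_info": self.training_info,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClockModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        doc = json.loads(text)
        if doc.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')}")
        return cls(
            sites=[CpGSite(c, int(p)) for c, p in doc["sites"]],
            weights=np.array(doc["weights"]),
            reference_quantiles=np.array(doc["reference_quantiles"]),
            site_means=np.array(doc["site_means"]),
            site_sds=np.array(doc["site_sds"]),
            calibration=tuple(doc["calibration"]),
            age_offset_weeks=float(doc["age_offset_weeks"]),
            alpha=doc.get("alpha"),
            lam=doc.get("lambda"),
            training_info=doc.get("training_info", {}),
        )

    @classmethod
    def from_site_table(cls, table: pd.DataFrame,
                        calibration: tuple[float, float, float],
                        reference_quantiles: np.ndarray | None = None,
                        site_means: np.ndarray | None = None,
                        site_sds: np.ndarray | None = None,
                        age_offset_weeks: float = 3.0,
                        training_info: dict | None = None) -> "ClockModel":
        """Build a model from a published site/weight table.

        ``table`` needs columns chrom, pos, weight.  Normalization pieces
        default to an uninformative identity (uniform reference, mean 0.5,
        sd 1) when the publication does not ship them; predictions through
        such a model are score-level only until a reference is supplied.
        """
        k = len(table)
        sites = [CpGSite(str(r["chrom"]), int(r["pos"])) for _, r in table.iterrows()]
        return cls(
            sites=sites,
            weights=table["weight"].to_numpy(dtype=float),
            reference_quantiles=np.linspace(0, 1, 1001) if reference_quantiles is None else reference_quantiles,
            site_means=np.full(k, 0.5) if site_means is None else site_means,
            site_sds=np.ones(k) if site_sds is None else site_sds,
            calibration=calibration,
            age_offset_weeks=age_offset_weeks,
            training_info=training_info or {"source": "site table"},
        )

    def sites_table(self) -> pd.DataFrame:
        """Selected sites and weights, TSV-ready."""
        return pd.DataFrame({
            "chrom": [s.chrom for s in self.sites],
            "pos": [s.pos for s in self.sites],
            "weight": self.weights,
        })


def train_clock(matrix: MethylationMatrix, meta: Sequence[SampleMeta], *,
                alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                n_folds: int = 10, outer_folds: int = 10, min_cov: int = 5,
                age_offset_weeks: float = 3.0, seed: int = 0,
                stratify_by_dataset: bool = True) -> ClockModel:
    """Full training pipeline on a merged multi-sample matrix.

    After the elastic net selects sites, the stored per-site means/sds and
    the calibration are computed through the same single-sample quantile
    mapping that prediction uses, so a training sample pushed through the
    serialized model reproduces its in-training fitted value exactly.
    """
    by_id = {m.sample_id: m for m in meta}
    samples = [s for s in matrix.samples if s in by_id]
    if len(samples) < len(matrix.samples):
        warnings.warn(f"{len(matrix.samples) - len(samples)} samples lack metadata; dropped")
    matrix = matrix.subset_samples(samples)
    ages = np.array([by_id[s].age_weeks for s in samples], dtype=float)
    y = transform_age(ages, age_offset_weeks)
    strata = [by_id[s].dataset for s in samples] if stratify_by_dataset else None

    idx = intersect_usable_sites([matrix], min_cov=min_cov)
    frac = matrix.subset_sites(idx).fraction
    qn, reference = quantile_normalize(frac)
    sds = qn.to_numpy().std(axis=1, ddof=1)
    qn = qn.loc[sds > 0]
    z, _, _ = standardize(qn)

    w, alpha, lam, report = train_elastic_net(z, y, alpha_grid, n_folds, seed,
                                              outer_folds=outer_folds, strata=strata)
    sel = np.where(w != 0)[0]
    if sel.size == 0:
        raise ValueError("elastic net selected no sites; data carry no age signal at this penalty")

    sel_index = z.index[sel]
    raw_frac = frac.loc[sel_index].to_numpy()  # selected sites x samples
    mapped = np.column_stack([
        map_sample_to_reference(raw_frac[:, j], reference) for j in range(raw_frac.shape[1])
    ])
    means = mapped.mean(axis=1)
    sds_sel = mapped.std(axis=1, ddof=1)
    ok = sds_sel > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} selected sites constant under the predict-time mapping")
    sel_index = sel_index[ok]
    weights = w[sel][ok]
    mapped, means, sds_sel = mapped[ok], means[ok], sds_sel[ok]

    zs = (mapped - means[:, None]) / sds_sel[:, None]
    x_scores = weights @ zs
    calibration = fit_quadratic(x_scores, y)

    return ClockModel(
        sites=[CpGSite(c, int(p)) for c, p in sel_index],
        weights=weights,
        reference_quantiles=reference,
        site_means=means,
        site_sds=sds_sel,
        calibration=calibration,
        age_offset_weeks=age_offset_weeks,
        alpha=alpha,
        lam=lam,
        training_info={
            "n_samples": len(samples),
            "n_intersected_sites": int(len(idx)),
            "seed": seed,
            "alpha_grid": list(map(float, alpha_grid)),
            "cv": report.as_dict(),
        },
    )
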