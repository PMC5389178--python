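"""Region-aggregated age prediction (cross-species comparison).

To ask whether regions defined in another species (e.g. human clock CpGs
lifted over to the mouse genome) carry age information, CpG-level
methylation is averaged within genomic regions and a ridge model (elastic
net with mixing parameter fixed to 0) is trained on the region values with
the same normalization and quadratic-calibration machinery as the
site-level clock.  A null distribution of test MAEs from models built on
random region subsets (sampled regardless of coverage) quantifies how
unusual a focal region set's accuracy is.

Region coordinates are inputs (BED, 0-based half-open); producing them
with liftover tooling is upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._linear import (cv_select, fit_at, fit_quadratic, map_sample_to_reference,
                      quantile_normalize, standardize)
from .evaluation import mae_weeks
from .io_rrbs import MethylationMatrix
from .regions import RegionSet, read_bed  # noqa: F401 (re-export)

__all__ = [
    "RegionSet",
    "read_bed",
    "aggregate_regions",
    "RegionClockModel",
    "train_region_ridge",
    "predict_regions",
    "random_region_null",
]


def aggregate_regions(matrix: MethylationMatrix, regions: RegionSet,
                      weighting: str = "unweighted") -> pd.DataFrame:
    """Region x sample mean methylation fractions.

    A region's value in a sample is the mean fraction over its member CpGs
    (``weighting="coverage"`` weights by read counts); it is missing when no
    member CpG is covered in that sample.  Regions containing no CpG in any
    sample are dropped; the count is reported in ``.attrs['n_dropped']``.
    """
    if weighting not in ("unweighted", "coverage"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    meth = matrix.meth.to_numpy(dtype=float)
    total = matrix.total.to_numpy(dtype=float)
    n_regions = len(regions)
    n_samples = len(matrix.samples)
    num = np.zeros((n_regions, n_samples))
    den = np.zeros((n_regions, n_samples))
    covered_any = np.zeros(n_regions, dtype=bool)
    for i, (chrom, pos) in enumerate(matrix.meth.index):
        hits = regions.overlapping(chrom, int(pos))
        if not hits:
            continue
        t = total[i]
        ok = t > 0
        if not ok.any():
            continue
        frac = np.where(ok, meth[i] / np.where(ok, t, 1.0), 0.0)
        w = t if weighting == "coverage" else ok.astype(float)
        for r in hits:
            covered_any[r] = True
            num[r] += w * frac
            den[r] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / den, np.nan)
    out = pd.DataFrame(vals[covered_any],
                       index=pd.Index(regions.regions["name"][covered_any], name="region"),
                       columns=matrix.samples)
    out.attrs["n_dropped"] = int((~covered_any).sum())
    return out


@dataclass
class RegionClockModel:
    """Ridge clock over region-mean methylation values."""

    region_names: list[str]
    weights: np.ndarray
    reference_quantiles: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    calibration: tuple[float, float, float]
    age_offset_weeks: float = 3.0
    lam: float | None = None
    training_info: dict = field(default_factory=dict)


def train_region_ridge(region_matrix: pd.DataFrame, log_ages: Sequence[float],
                       n_folds: int = 10, seed: int = 0, *,
                       age_offset_weeks: float = 3.0) -> RegionClockModel:
    """Ridge regression on a complete region x sample matrix.

    Rows with any missing value are dropped first (a region uncovered in
    one sample cannot enter the model).  Lambda is chosen by seeded K-fold
    CV; normalization and quadratic calibration mirror the site-level clock.
    """
    y = np.asarray(log_ages, dtype=float)
    complete = region_matrix.dropna(axis=0)
    n_dropped = len(region_matrix) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} regions with missing values before ridge training")
    if complete.empty:
        raise ValueError("no complete regions to train on")
    qn, reference = quantile_normalize(complete)
    sds0 = qn.to_numpy().std(axis=1, ddof=1)
    qn = qn.loc[sds0 > 0]
    z, _, _ = standardize(qn)
    X = z.to_numpy().T
    _, lam, _ = cv_select(X, y, [0.0], n_folds, seed)
    w, _ = fit_at(X, y, 0.0, lam)

    raw = complete.loc[z.index].to_numpy()
    mapped = np.column_stack([map_sample_to_reference(raw[:, j], reference)
                              for j in range(raw.shape[1])])
    means = mapped.mean(axis=1)
    sds = mapped.std(axis=1, ddof=1)
    ok = sds > 0
    names = [str(n) for n in z.index[ok]]
    w, mapped, means, sds = w[ok], mapped[ok], means[ok], sds[ok]
    x_scores = w @ ((mapped - means[:, None]) / sds[:, None])
    calibration = fit_quadratic(x_scores, y)
    return RegionClockModel(
        region_names=names, weights=w, reference_quantiles=np.sort(reference),
        means=means, sds=sds, calibration=calibration,
        age_offset_weeks=age_offset_weeks, lam=lam,
        training_info={"n_regions": len(names), "n_dropped": n_dropped,
                       "n_samples": X.shape[0], "seed": seed},
    )


def predict_regions(model: RegionClockModel, region_matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply a region clock to a region x sample matrix.

    Regions missing in a sample contribute their training mean (z = 0).
    """
    a, b, c = model.calibration
    rows = []
    sub = region_matrix.reindex(model.region_names)
    for sid in region_matrix.columns:
        vals = sub[sid].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        z = np.zeros(len(model.region_names))
        if ok.any():
            mapped = map_sample_to_reference(vals[ok], model.reference_quantiles)
            z[ok] = (mapped - model.means[ok]) / model.sds[ok]
        x = float(model.weights @ z)
        log_age = a * x * x + b * x + c
        rows.append({"sample_id": sid, "raw_score": x, "log_age": log_age,
                     "predicted_age_weeks": float(np.exp(log_age) - model.age_offset_weeks),
                     "n_regions_used": int(ok.sum())})
    return pd.DataFrame(rows)


def random_region_null(matrix: MethylationMatrix, universe: RegionSet,
                       log_ages_train: Sequence[float], train_samples: Sequence[str],
                       test_samples: Sequence[str], ages_test_weeks: Sequence[float],
                       *, k: int = 329, n_models: int = 1000, seed: int = 0,
                       n_folds: int = 10, focal_mae: float | None = None) -> dict:
    """Null distribution of test MAEs from models on random region subsets.

    Each replicate samples ``k`` regions from the universe without
    replacement — regardless of coverage; uncovered or incomplete regions
    are dropped before training and the drop counts are reported — trains a
    region ridge on the training samples and records the median absolute
    error (weeks) on the test samples.
    """
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    train_mat = matrix.subset_samples(list(train_samples))
    test_mat = matrix.subset_samples(list(test_samples))
    maes = np.empty(n_models)
    dropped = np.empty(n_models, dtype=int)
    for r in range(n_models):
        pick = rng.choice(len(universe), size=k, replace=False)
        rs = universe.subset(sorted(pick), label=f"null_{r}")
        agg_train = aggregate_regions(train_mat, rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_region_ridge(agg_train, log_ages_train,
                                       n_folds=n_folds, seed=int(rng.integers(2**31 - 1)))
        dropped[r] = (k - len(model.region_names))
        agg_test = aggregate_regions(test_mat, rs)
        pred = predict_regions(model, agg_test).set_index("sample_id")
        p = pred.loc[list(test_samples), "predicted_age_weeks"].to_numpy()
        maes[r], _, _ = mae_weeks(p, np.asarray(ages_test_weeks, dtype=float))
    out = {
        "maes": maes,
        "mean": float(maes.mean()),
        "quantiles": {q: float(np.quantile(maes, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
        "n_dropped_regions": dropped,
    }
    if focal_mae is not None:
        out["focal_mae"] = float(focal_mae)
        out["focal_percentile"] = float(100.0 * np.mean(maes <= focal_mae))
    return out
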