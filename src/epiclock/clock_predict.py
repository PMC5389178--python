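"""Applying a trained clock to new samples.

A sample's methylation fractions at the model's CpG sites are mapped by
within-sample rank onto the model's stored training reference distribution
(linear interpolation), z-scored with the stored per-site means/sds, and
combined into the raw score x = sum_i beta_i z_i.  The quadratic
calibration then gives log(age + offset) and the predicted age in weeks is
exp(.) - offset.

Sites below the coverage floor are "missing": the ``error`` policy aborts
with the site list, ``mean_impute`` substitutes the training mean (z = 0)
with a warning, refusing to predict when more than 20% of model sites are
missing (the prediction would be dominated by imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._linear import map_sample_to_reference
from .clock_train import ClockModel
from .io_rrbs import MethylationMatrix, SampleMeta

__all__ = ["AgePrediction", "MissingSitesError", "predict_age", "predict_batch"]

_MAX_MISSING_FRAC = 0.20


class MissingSitesError(ValueError):
    def __init__(self, sample_id: str, missing: list):
        self.missing = missing
        shown = ", ".join(f"{c}:{p}" for c, p in missing[:8])
        more = "" if len(missing) <= 8 else f" (+{len(missing) - 8} more)"
        super().__init__(f"sample {sample_id!r}: {len(missing)} model sites missing: {shown}{more}")


@dataclass(frozen=True)
class AgePrediction:
    sample_id: str
    raw_score: float
    log_age: float
    predicted_age_weeks: float
    n_sites_used: int
    n_sites_missing: int


def predict_age(model: ClockModel, sample: MethylationMatrix, *,
                sample_id: str | None = None,
                missing_policy: Literal["error", "mean_impute"] = "error",
                min_cov: int = 5) -> AgePrediction:
    """Predict age for one sample (single-column matrix)."""
    if sample_id is None:
        if len(sample.samples) != 1:
            raise ValueError("matrix has several samples; pass sample_id")
        sample_id = sample.samples[0]

    site_index = pd.MultiIndex.from_tuples([(s.chrom, s.pos) for s in model.sites],
                                           names=["chrom", "pos"])
    total = sample.total[sample_id].reindex(site_index).fillna(0).to_numpy()
    meth = sample.meth[sample_id].reindex(site_index).fillna(0).to_numpy()
    usable = total >= min_cov
    missing = [tuple(site_index[i]) for i in np.where(~usable)[0]]
    if missing:
        if missing_policy == "error":
            raise MissingSitesError(sample_id, missing)
        if missing_policy != "mean_impute":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        if len(missing) / len(site_index) > _MAX_MISSING_FRAC:
            raise MissingSitesError(
                sample_id, missing) from ValueError("more than 20% of model sites missing")
        warnings.warn(f"sample {sample_id!r}: imputing training mean at {len(missing)} missing sites")

    z = np.zeros(len(site_index))
    if usable.any():
        frac = meth[usable] / total[usable]
        mapped = map_sample_to_reference(frac, model.reference_quantiles)
        z[usable] = (mapped - model.site_means[usable]) / model.site_sds[usable]

    x = float(model.weights @ z)
    a, b, _ = model.calibration
    if 2 * a * x + b <= 0:
        warnings.warn(
            f"sample {sample_id!r}: raw score {x:.3f} falls where the calibration "
            "quadratic is non-increasing; prediction may be outside the supported range"
        )
    log_age = model.calibrate(x)
    return AgePrediction(
        sample_id=sample_id,
        raw_score=x,
        log_age=float(log_age),
        predicted_age_weeks=float(np.exp(log_age) - model.age_offset_weeks),
        n_sites_used=int(usable.sum()),
        n_sites_missing=len(missing),
    )


def predict_batch(model: ClockModel, matrices: MethylationMatrix | Sequence[MethylationMatrix],
                  meta: Sequence[SampleMeta] | None = None, *,
                  missing_policy: Literal["error", "mean_impute"] = "error",
                  min_cov: int = 5) -> pd.DataFrame:
    """Predict every sample; per-sample failures become flagged rows.

    Returns one row per sample in deterministic (input) order with columns
    sample_id, raw_score, log_age, predicted_age_weeks, n_sites_used,
    n_sites_missing, error, and — when metadata is given — age_weeks and
    residual_weeks (predicted - actual).
    """
    if isinstance(matrices, MethylationMatrix):
        matrices = [matrices]
    by_id = {m.sample_id: m for m in (meta or [])}
    rows = []
    for mat in matrices:
        for sid in mat.samples:
            try:
                p = predict_age(model, mat, sample_id=sid,
                                missing_policy=missing_policy, min_cov=min_cov)
                row = {"sample_id": sid, "raw_score": p.raw_score, "log_age": p.log_age,
                       "predicted_age_weeks": p.predicted_age_weeks,
                       "n_sites_used": p.n_sites_used, "n_sites_missing": p.n_sites_missing,
                       "error": ""}
            except (MissingSitesError, ValueError) as exc:
                row = {"sample_id": sid, "raw_score": np.nan, "log_age": np.nan,
                       "predicted_age_weeks": np.nan, "n_sites_used": 0,
                       "n_sites_missing": model.n_sites, "error": str(exc)}
            if sid in by_id:
                row["age_weeks"] = by_id[sid].age_weeks
                row["residual_weeks"] = row["predicted_age_weeks"] - by_id[sid].age_weeks
            rows.append(row)
    return pd.DataFrame(rows)
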