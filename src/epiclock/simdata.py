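"""Synthetic multi-tissue RRBS aging methylomes.

Generates sites x samples methylation count matrices with the statistical
structure a multi-tissue methylation clock assumes:

* a bimodal per-site baseline (RRBS enriches CpG islands, so many sites are
  near-unmethylated and many near-fully methylated), calibrated so the
  global mean methylation matches a configured adult level (~45%), with
  newborn samples globally hypomethylated (~43%);
* tissue-specific offsets on the logit scale (tissue signatures);
* a minority of "planted" sites whose methylation moves monotonically with
  log(age + 3 weeks), half gaining and half losing methylation;
* integer read counts: per-site coverage drawn negative-binomially and
  methylated counts drawn beta-binomially around the sample's true fraction.

The default design mirrors a four-tissue, four-age study (newborn, 14, 27
and 41 weeks).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_rrbs import CpGSite, MethylationMatrix, SampleMeta, write_bismark_cov, write_metadata

__all__ = ["SyntheticConfig", "simulate_methylome", "write_fixture"]

_AUTOSOMES = [f"chr{i}" for i in range(1, 20)]  # mouse autosomes


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic methylome.

    ``effect_size`` is the absolute slope of planted sites on the logit
    scale per unit log(age_weeks + 3); over the default 0-41-week design
    log(age+3) spans ~2.7, so the default slope of 1.0 moves a mid-range
    site by roughly 50 percentage points across life.
    """

    n_sites: int = 2000
    n_samples_per_group: int = 4
    tissues: tuple[str, ...] = ("liver", "lung", "heart", "cortex")
    ages_weeks: tuple[float, ...] = (0.0, 14.0, 27.0, 41.0)
    frac_age_sites: float = 0.10
    effect_size: float = 1.0
    tissue_sd: float = 0.4
    adult_global_mean: float = 0.45
    newborn_global_mean: float = 0.43
    newborn_global_shift: float | None = None  # logit shift; None = calibrated
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.3  # NB: var = mu + dispersion * mu^2
    bb_precision: float = 80.0        # beta-binomial concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_age_sites <= 1.0):
            raise ValueError("frac_age_sites must be in [0, 1]")
        if self.n_sites <= 0 or self.n_samples_per_group <= 0 or not self.tissues or not self.ages_weeks:
            raise ValueError("degenerate config: sites, samples, tissues and ages must be non-empty")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0 or self.bb_precision <= 0:
            raise ValueError("coverage_mean, coverage_dispersion and bb_precision must be positive")


def _calibrate_shift(base_logit: np.ndarray, target_mean: float) -> float:
    """Constant logit shift making mean(sigmoid(base + shift)) == target."""
    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(base_logit + mid).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_methylome(config: SyntheticConfig) -> tuple[MethylationMatrix, list[SampleMeta], pd.DataFrame]:
    """Simulate a methylome; returns (matrix, metadata, planted-site truth table).

    The truth table has one row per planted site with its chrom, pos, sign
    and logit-scale slope; it is empty when ``frac_age_sites == 0``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # site coordinates: autosomes, unique ascending positions per chromosome
    chrom_idx = rng.integers(0, len(_AUTOSOMES), size=cfg.n_sites)
    chroms = np.array(_AUTOSOMES, dtype=object)[chrom_idx]
    pos = np.zeros(cfg.n_sites, dtype=np.int64)
    for c in _AUTOSOMES:
        mask = chroms == c
        n = int(mask.sum())
        if n:
            pos[mask] = np.sort(rng.choice(np.arange(3_000_000, 3_000_000 + 60 * cfg.n_sites, 2), size=n, replace=False))
    sites = [CpGSite(c, int(p)) for c, p in zip(chroms, pos)]
    order = np.lexsort((pos, chroms.astype(str)))
    sites = [sites[i] for i in order]

    # bimodal RRBS-like baseline on the logit scale, calibrated to the adult mean
    comp = rng.choice(3, size=cfg.n_sites, p=[0.40, 0.40, 0.20])
    base = np.where(comp == 0, rng.normal(logit(0.06), 0.9, cfg.n_sites),
                    np.where(comp == 1, rng.normal(logit(0.92), 0.9, cfg.n_sites),
                             rng.normal(0.0, 1.2, cfg.n_sites)))
    base = base + _calibrate_shift(base, cfg.adult_global_mean)

    # planted age trajectories, centred at mean log-age so the global level is stable
    n_planted = int(round(cfg.frac_age_sites * cfg.n_sites))
    planted = rng.choice(cfg.n_sites, size=n_planted, replace=False)
    signs = np.ones(n_planted)
    signs[rng.permutation(n_planted)[: n_planted // 2]] = -1.0
    slopes = np.zeros(cfg.n_sites)
    slopes[planted] = signs * cfg.effect_size

    # tissue signatures
    tissue_offset = {t: rng.normal(0.0, cfg.tissue_sd, cfg.n_sites) for t in cfg.tissues}

    if cfg.newborn_global_shift is None:
        newborn_shift = _calibrate_shift(base, cfg.newborn_global_mean) - _calibrate_shift(base, cfg.adult_global_mean)
    else:
        newborn_shift = cfg.newborn_global_shift

    log_ages = np.log(np.asarray(cfg.ages_weeks) + 3.0)
    center = log_ages.mean()

    meta: list[SampleMeta] = []
    columns: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sexes = ("F", "M")
    for tissue in cfg.tissues:
        for age, la in zip(cfg.ages_weeks, log_ages):
            for rep in range(cfg.n_samples_per_group):
                sid = f"{tissue}_{age:g}w_r{rep + 1}"
                true_logit = base + tissue_offset[tissue] + slopes * (la - center)
                if age == 0:
                    true_logit = true_logit + newborn_shift
                p_true = expit(true_logit)
                # beta-binomial counts over NB coverage
                size = 1.0 / cfg.coverage_dispersion
                cov = rng.negative_binomial(size, size / (size + cfg.coverage_mean), cfg.n_sites)
                a = np.clip(p_true * cfg.bb_precision, 1e-6, None)
                b = np.clip((1.0 - p_true) * cfg.bb_precision, 1e-6, None)
                p_cell = rng.beta(a, b)
                m = rng.binomial(cov, p_cell)
                columns[sid] = (m, cov)
                meta.append(SampleMeta(sample_id=sid, age_weeks=float(age), tissue=tissue,
                                       sex=sexes[rep % 2], dataset="synthetic"))

    meth = np.column_stack([columns[m.sample_id][0] for m in meta])[order]
    total = np.column_stack([columns[m.sample_id][1] for m in meta])[order]
    matrix = MethylationMatrix.from_records(sites, [m.sample_id for m in meta], meth, total)

    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    truth = pd.DataFrame({
        "chrom": [sites[inv[i]].chrom for i in planted],
        "pos": [sites[inv[i]].pos for i in planted],
        "sign": np.sign(slopes[planted]).astype(int),
        "slope": slopes[planted],
    }).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return matrix, meta, truth


def write_fixture(directory: str | Path, matrix: MethylationMatrix,
                  meta: Sequence[SampleMeta], *, gzip_cov: bool = False) -> dict[str, Path]:
    """Write one Bismark coverage file per sample plus the metadata sheet.

    Returns a mapping of artefact names to paths; re-reading the files
    through :mod:`epiclock.io_rrbs` reproduces the matrix counts exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ext = ".cov.gz" if gzip_cov else ".cov"
    for m in meta:
        p = directory / f"{m.sample_id}{ext}"
        write_bismark_cov(matrix, p, sample=m.sample_id)
        paths[m.sample_id] = p
    sheet = directory / "samples.tsv"
    write_metadata(list(meta), sheet)
    paths["metadata"] = sheet
    return paths
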