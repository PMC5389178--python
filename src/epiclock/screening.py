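"""Site-level coverage filtering and age-correlation screening.

The screening stage asks, for every CpG site, whether its methylation
fraction correlates with chronological age (in days) across samples —
either over all tissues pooled or within one tissue.  Correlation is
Spearman's rho on average ranks.  P-values come from the exact permutation
null for small sample counts (n <= 9, as tissue-specific analyses can have
as few as four samples) and the asymptotic t-approximation otherwise.
Multiple-testing correction is Storey's q-value with a smoother-based pi0
estimate, falling back to pi0 = 1 (Benjamini-Hochberg-equivalent) when the
estimate is unstable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_rrbs import CpGSite, MethylationMatrix, SampleMeta

__all__ = [
    "CorrelationResult",
    "filter_sites",
    "spearman_age",
    "correct_q",
    "classify_directionality",
    "shared_tissue_count",
    "results_frame",
]


@dataclass(frozen=True)
class CorrelationResult:
    site: CpGSite
    rho: float
    p_value: float
    q_value: float | None
    n_used: int
    tissue: str = "all"


# ---------------------------------------------------------------------------
# coverage filtering

def filter_sites(matrix: MethylationMatrix, *, min_mean_cov: float = 2.0,
                 max_mean_cov: float = 100.0, per_sample_min_cov: int = 5,
                 min_frac_covered: float = 0.9) -> MethylationMatrix:
    """Apply the three coverage rules, in order.

    1. drop sites whose mean coverage across samples is < ``min_mean_cov``
       (spurious) or > ``max_mean_cov`` (mapping artefacts);
    2. blank cells covered by < ``per_sample_min_cov`` reads (set missing);
    3. drop sites defined in fewer than ``min_frac_covered`` of samples.

    Site order is preserved.
    """
    if min_mean_cov < 0 or max_mean_cov < min_mean_cov:
        raise ValueError("invalid mean-coverage bounds")
    if per_sample_min_cov < 0 or not (0.0 < min_frac_covered <= 1.0):
        raise ValueError("invalid per-sample thresholds")
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")

    total = matrix.total.to_numpy(dtype=float)
    meth = matrix.meth.to_numpy()
    mean_cov = total.mean(axis=1)
    keep = (mean_cov >= min_mean_cov) & (mean_cov <= max_mean_cov)
    total = total[keep].copy()
    meth = meth[keep].copy()
    low = total < per_sample_min_cov
    total[low] = 0
    meth[low] = 0
    frac_covered = (total > 0).mean(axis=1)
    keep2 = frac_covered >= min_frac_covered
    idx = matrix.meth.index[keep][keep2]
    return MethylationMatrix(
        pd.DataFrame(meth[keep2].astype(np.int64), index=idx, columns=matrix.samples),
        pd.DataFrame(total[keep2].astype(np.int64), index=idx, columns=matrix.samples),
    )


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n permutation p

_EXACT_MAX_N = 9
_null_cache: dict[tuple, np.ndarray] = {}


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def _exact_null_abs_rho(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """|rho| over all pairings of the two rank multisets (cached)."""
    key = (tuple(np.sort(rx)), tuple(np.sort(ry)))
    if key not in _null_cache:
        n = len(rx)
        perms = np.array(list(itertools.permutations(np.sort(ry))))
        a = np.sort(rx) - np.mean(rx)
        b = perms - np.mean(ry)
        denom = np.sqrt((a * a).sum() * (b * b).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = (b @ a) / denom
        _null_cache[key] = np.abs(np.nan_to_num(rhos))
    return _null_cache[key]


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks) and two-sided p-value.

    Exact permutation null for n <= 9; t-approximation otherwise.
    Returns (nan, nan) when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan
    if n <= _EXACT_MAX_N:
        null = _exact_null_abs_rho(rx, ry)
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            t = np.inf
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(np.clip(p, np.finfo(float).tiny, 1.0))


def spearman_age(matrix: MethylationMatrix, meta: Sequence[SampleMeta],
                 tissue: str = "all", min_samples: int = 4,
                 *, compute_q: bool = True) -> list[CorrelationResult]:
    """Per-site Spearman correlation of methylation fraction with age in days.

    ``tissue="all"`` pools every sample; otherwise only that tissue's samples
    are used.  Sites with fewer than ``min_samples`` usable values, or with
    zero variance in either variable, are dropped (no result).  Q-values are
    computed over the returned set unless ``compute_q`` is false.
    """
    by_id = {m.sample_id: m for m in meta}
    missing_meta = [s for s in matrix.samples if s not in by_id]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta[:5]}")
    if tissue == "all":
        use = list(matrix.samples)
    else:
        use = [s for s in matrix.samples if by_id[s].tissue == tissue]
        if not use:
            raise ValueError(f"unknown tissue {tissue!r}")
    ages = np.array([by_id[s].age_days for s in use], dtype=float)
    frac = matrix.fraction[use].to_numpy()

    results: list[CorrelationResult] = []
    index = matrix.meth.index
    for i in range(frac.shape[0]):
        row = frac[i]
        ok = ~np.isnan(row)
        n_used = int(ok.sum())
        if n_used < max(min_samples, 2):
            continue
        rho, p = spearman_test(row[ok], ages[ok])
        if np.isnan(rho):
            continue
        chrom, pos = index[i]
        results.append(CorrelationResult(CpGSite(chrom, int(pos)), rho, p, None, n_used, tissue))

    if compute_q and results:
        qs = correct_q([r.p_value for r in results])
        results = [CorrelationResult(r.site, r.rho, r.p_value, q, r.n_used, r.tissue)
                   for r, q in zip(results, qs)]
    return results


def results_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tabulate results as a TSV-ready frame (site, rho, p, q, n, tissue)."""
    return pd.DataFrame([{
        "chrom": r.site.chrom, "pos": r.site.pos, "rho": r.rho, "p_value": r.p_value,
        "q_value": r.q_value, "n_used": r.n_used, "tissue": r.tissue,
    } for r in results])


# ---------------------------------------------------------------------------
# Storey q-values

def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother-based estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fitted with a cubic
    polynomial smoother over lambda in {0.05, ..., 0.95} and evaluated at
    the largest lambda.  Estimates outside (0, 1] fall back to 1.
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0s = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.all(pi0s == 0):
        return 1.0
    coef = np.polyfit(lambdas, pi0s, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    if pi0 <= 0 or pi0 > 1:
        return 1.0
    return pi0


def correct_q(p_values: Sequence[float], *, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; monotone nondecreasing in p.

    With ``pi0`` forced to 1 this reduces to Benjamini-Hochberg adjusted
    p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# directionality across analyses and cross-tissue sharing

def classify_directionality(all_ages_results: Sequence[CorrelationResult],
                            adult_only_results: Sequence[CorrelationResult],
                            nominal_p: float = 0.05) -> dict[CpGSite, str]:
    """Compare correlation direction with and without newborn samples.

    concordant_{positive,negative}: the signs agree and at least one analysis
    is nominally significant; reversed: the signs differ (both nonzero);
    unstable: anything else.  Sites present in only one analysis get no label.
    """
    a = {r.site: r for r in all_ages_results}
    b = {r.site: r for r in adult_only_results}
    labels: dict[CpGSite, str] = {}
    for site in a.keys() & b.keys():
        ra, rb = a[site], b[site]
        sa, sb = np.sign(ra.rho), np.sign(rb.rho)
        nominal = ra.p_value < nominal_p or rb.p_value < nominal_p
        if sa != 0 and sa == sb and nominal:
            labels[site] = "concordant_positive" if sa > 0 else "concordant_negative"
        elif sa * sb < 0:
            labels[site] = "reversed"
        else:
            labels[site] = "unstable"
    return labels


def shared_tissue_count(per_tissue_results: Mapping[str, Sequence[CorrelationResult]],
                        threshold_p: float = 0.05) -> dict[CpGSite, int]:
    """Number of tissues in which each site is nominally age-correlated."""
    if len(per_tissue_results) < 2:
        raise ValueError("need results for at least two tissues")
    counts: dict[CpGSite, int] = {}
    for results in per_tissue_results.values():
        for r in results:
            counts.setdefault(r.site, 0)
            if r.p_value < threshold_p:
                counts[r.site] += 1
    return counts
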