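"""Sequence and annotation context of age-correlated CpG sites.

Implements the descriptive statistics used to characterise significant
sites against the covered-CpG background: CpG scarcity (window size over
the number of CpGs in a window centred on a focal CpG), normalized-
likelihood enrichment over genomic elements (CpG islands, shores, shelves,
promoter classes, ...), exact binomial enrichment tests, scarcity t-tests
per correlation sign, ROC AUC of CpG density as a predictor of
significance, and the neighbouring-gene export (genes within 4 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_rrbs import CpGSite
from .regions import RegionSet

__all__ = [
    "EnrichmentResult",
    "UndefinedEnrichment",
    "positions_by_chrom",
    "cpg_scarcity",
    "normalized_likelihood",
    "category_enrichment",
    "density_auc",
    "scarcity_group_tests",
    "neighbouring_genes",
]


class UndefinedEnrichment(ValueError):
    """Enrichment is undefined (empty background category or no significant sites)."""


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    s: int              # significant sites in category
    S: int              # all significant sites
    b: int              # background sites in category
    B: int              # all background sites
    normalized_likelihood: float  # (s/b)(B/S) - 1; NaN when undefined
    binomial_p: float             # two-sided exact binomial p; NaN when undefined


def positions_by_chrom(sites: Sequence[CpGSite]) -> dict[str, np.ndarray]:
    """Sorted 1-based position arrays per chromosome."""
    out: dict[str, list[int]] = {}
    for s in sites:
        out.setdefault(s.chrom, []).append(s.pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in out.items()}


def cpg_scarcity(all_positions: Mapping[str, np.ndarray], focal: CpGSite,
                 window_bp: int = 200) -> float:
    """window_bp / number of CpGs within a window_bp window centred on focal.

    The focal site itself is counted, so the result is at most ``window_bp``.
    High values mean CpG-poor context.  The default 200 bp window has a 1 kb
    variant (window_bp=1000) used for density plots.
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be even and positive")
    pos = all_positions.get(focal.chrom)
    if pos is None:
        raise ValueError(f"focal chromosome {focal.chrom!r} not in site universe")
    half = window_bp // 2
    lo = np.searchsorted(pos, focal.pos - half, side="left")
    hi = np.searchsorted(pos, focal.pos + half, side="right")
    if np.searchsorted(pos, focal.pos, side="right") - np.searchsorted(pos, focal.pos, side="left") == 0:
        raise ValueError(f"focal site {focal.chrom}:{focal.pos} not in site universe")
    return window_bp / float(hi - lo)


def normalized_likelihood(s: int, b: int, S: int, B: int) -> float:
    """(s/b) * (B/S) - 1: excess of significant sites in a category.

    0 means significant sites mirror the background; positive values mean
    enrichment.  Undefined (raises) when b == 0 or S == 0.
    """
    if B <= 0:
        raise UndefinedEnrichment("empty background")
    if b == 0:
        raise UndefinedEnrichment("no background sites in category")
    if S == 0:
        raise UndefinedEnrichment("no significant sites")
    if s > S or b > B:
        raise ValueError("category counts exceed totals")
    return (s / b) * (B / S) - 1.0


def category_enrichment(sig_sites: Sequence[CpGSite], background: Sequence[CpGSite],
                        features: Mapping[str, RegionSet]) -> list[EnrichmentResult]:
    """Per-category enrichment of significant sites against the background.

    Membership is interval overlap (BED half-open convention).  The binomial
    test treats the S significant sites as trials with success rate b/B from
    the background.  Categories with an empty background yield NaN statistics.
    """
    S, B = len(sig_sites), len(background)
    if B == 0:
        raise ValueError("empty background")
    out: list[EnrichmentResult] = []
    for name, rs in features.items():
        s = sum(rs.contains(x.chrom, x.pos) for x in sig_sites)
        b = sum(rs.contains(x.chrom, x.pos) for x in background)
        try:
            nl = normalized_likelihood(s, b, S, B)
            p = float(stats.binomtest(s, S, b / B, alternative="two-sided").pvalue)
        except UndefinedEnrichment:
            nl, p = np.nan, np.nan
        out.append(EnrichmentResult(name, s, S, b, B, nl, p))
    return out


def density_auc(scores: Sequence[float], is_significant: Sequence[bool]) -> float:
    """Rank-based AUC of a score for separating significant from other sites.

    Probability that a significant site's score exceeds a non-significant
    one's, ties counted half (Mann-Whitney U over n1*n0).
    """
    scores = np.asarray(scores, dtype=float)
    sig = np.asarray(is_significant, dtype=bool)
    n1, n0 = int(sig.sum()), int((~sig).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[sig].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def scarcity_group_tests(scarcity: Mapping[CpGSite, float],
                         groups: Mapping[str, Sequence[CpGSite]],
                         background: Sequence[CpGSite],
                         *, equal_var: bool = False) -> pd.DataFrame:
    """Two-sample t-tests of each significant class vs the background.

    Returns per-group mean scarcity, t, raw p and Bonferroni-corrected p
    (corrected over the number of groups).
    """
    bg = np.array([scarcity[s] for s in background], dtype=float)
    rows = []
    k = len(groups)
    for name, sites in groups.items():
        vals = np.array([scarcity[s] for s in sites], dtype=float)
        t, p = stats.ttest_ind(vals, bg, equal_var=equal_var)
        rows.append({"group": name, "n": len(vals), "mean_scarcity": vals.mean(),
                     "background_mean": bg.mean(), "t": float(t), "p": float(p),
                     "p_bonferroni": float(min(1.0, p * k))})
    return pd.DataFrame(rows)


def neighbouring_genes(sites: Sequence[CpGSite], genes: RegionSet,
                       max_dist: int = 4000) -> pd.DataFrame:
    """Genes whose interval lies within ``max_dist`` bp of each site.

    One row per (site, gene) pair; used to hand gene lists to external
    ontology tools, which are outside the scope of this package.
    """
    rows = []
    for s in sites:
        for i in genes.near(s.chrom, s.pos, max_dist):
            g = genes.regions.iloc[i]
            rows.append({"chrom": s.chrom, "pos": s.pos, "gene": g["name"],
                         "gene_start": int(g["start"]), "gene_end": int(g["end"])})
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene", "gene_start", "gene_end"])
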