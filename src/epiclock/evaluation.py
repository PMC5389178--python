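"""Accuracy and biological-age evaluation of clock predictions.

Accuracy is summarized by the MEDIAN absolute error (MAE) in weeks —
overall and split into young (< 20 weeks by default) and old strata — and
by the correlation of predicted with chronological age.  Biological-age
analyses work on residuals (predicted - actual age, "age acceleration"):
an unpaired two-tailed t-test for one grouping factor (Welch by default)
and a two-way ANOVA with interaction for two factors.  Exploratory
structure is exposed via hierarchical clustering with Manhattan distances
and a PCA of the clock-site matrix with per-component age association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io_rrbs import MethylationMatrix
from .screening import spearman_test

__all__ = [
    "EvaluationReport",
    "mae_weeks",
    "age_correlation",
    "age_acceleration_test",
    "cluster_samples",
    "pca_clock_sites",
    "evaluate_predictions",
]


def mae_weeks(predicted: Sequence[float], actual: Sequence[float],
              age_split_weeks: float = 20.0) -> tuple[float, float, float]:
    """Median absolute error overall and within young/old strata.

    Young: actual < ``age_split_weeks``; old: actual >= split.  An empty
    stratum yields NaN, never 0.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    err = np.abs(predicted - actual)
    young = actual < age_split_weeks
    mae = float(np.median(err))
    mae_young = float(np.median(err[young])) if young.any() else np.nan
    mae_old = float(np.median(err[~young])) if (~young).any() else np.nan
    return mae, mae_young, mae_old


def age_correlation(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Pearson correlation of predicted with chronological age."""
    r = np.corrcoef(np.asarray(predicted, float), np.asarray(actual, float))[0, 1]
    return float(r)


@dataclass
class EvaluationReport:
    mae_weeks: float
    mae_young: float
    mae_old: float
    age_correlation: float
    n_samples: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def evaluate_predictions(table: pd.DataFrame, age_split_weeks: float = 20.0) -> EvaluationReport:
    """Summarize a prediction table (as from ``predict_batch`` with metadata)."""
    ok = table[table["error"] == ""] if "error" in table.columns else table
    pred = ok["predicted_age_weeks"].to_numpy(dtype=float)
    act = ok["age_weeks"].to_numpy(dtype=float)
    mae, my, mo = mae_weeks(pred, act, age_split_weeks)
    return EvaluationReport(mae, my, mo, age_correlation(pred, act), len(ok))


def age_acceleration_test(residuals: Sequence[float], groups: pd.DataFrame | Sequence,
                          *, equal_var: bool = False) -> dict:
    """Test whether age acceleration differs between groups.

    One grouping factor (a sequence or single-column frame): unpaired
    two-tailed t-test on the residuals, Welch by default (``equal_var=True``
    gives the classical pooled test).  Two factors (two-column frame):
    two-way ANOVA with interaction, type-II sums of squares, returning the
    two main-effect and the interaction p-values.
    """
    resid = np.asarray(residuals, dtype=float)
    if isinstance(groups, pd.DataFrame):
        factors = groups
    else:
        factors = pd.DataFrame({"group": list(groups)})
    if len(factors) != len(resid):
        raise ValueError("groups and residuals must align")

    if factors.shape[1] == 1:
        col = factors.columns[0]
        levels = pd.unique(factors[col])
        if len(levels) != 2:
            raise ValueError(f"one-factor test needs exactly 2 groups, got {len(levels)}")
        a = resid[factors[col] == levels[0]]
        b = resid[factors[col] == levels[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        return {
            "test": "t" if equal_var else "welch_t",
            "groups": {str(levels[0]): {"n": len(a), "mean_residual": float(a.mean())},
                       str(levels[1]): {"n": len(b), "mean_residual": float(b.mean())}},
            "statistic": float(t),
            "p_value": float(p),
        }
    if factors.shape[1] == 2:
        f1, f2 = factors.columns
        df = factors.copy()
        df["resid"] = resid
        counts = df.groupby([f1, f2], observed=True).size()
        if (counts < 2).any():
            raise ValueError("every cell of the two-way design needs n >= 2")
        model = smf.ols(f"resid ~ C({f1}) * C({f2})", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        return {
            "test": "two_way_anova_type2",
            "p_values": {
                str(f1): float(table.loc[f"C({f1})", "PR(>F)"]),
                str(f2): float(table.loc[f"C({f2})", "PR(>F)"]),
                "interaction": float(table.loc[f"C({f1}):C({f2})", "PR(>F)"]),
            },
            "anova_table": table,
        }
    raise ValueError("groups must have one or two factors")


def cluster_samples(matrix: MethylationMatrix, *, method: str = "complete") -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples on Manhattan distances.

    Samples are ordered lexicographically before computing distances so the
    dendrogram is deterministic.  Requires complete methylation fractions
    on the clustering site set.  Returns (scipy linkage matrix, labels).
    """
    labels = sorted(matrix.samples)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    frac = matrix.fraction[labels].to_numpy().T  # samples x sites
    if np.isnan(frac).any():
        raise ValueError("missing cells; restrict to fully covered sites first")
    d = pdist(frac, metric="cityblock")
    return linkage(d, method=method), labels


def pca_clock_sites(values: pd.DataFrame, ages_weeks: Sequence[float]) -> dict:
    """Centered PCA of a sites x samples matrix with per-PC age association.

    Returns component scores (samples x components), variance-explained
    fractions (summing to 1 over all components) and a per-component
    Spearman test against age.
    """
    X = values.to_numpy(dtype=float).T  # samples x sites
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    ages = np.asarray(ages_weeks, dtype=float)
    if len(ages) != n:
        raise ValueError("ages must align with samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    keep = var > var.max() * 1e-12 if var.max() > 0 else np.zeros_like(var, dtype=bool)
    scores = U[:, keep] * s[keep]
    explained = var[keep] / var[keep].sum()
    assoc = [spearman_test(scores[:, i], ages) for i in range(scores.shape[1])]
    return {
        "scores": pd.DataFrame(scores, index=values.columns,
                               columns=[f"PC{i + 1}" for i in range(scores.shape[1])]),
        "variance_explained": explained,
        "age_association": pd.DataFrame(
            {"rho": [a[0] for a in assoc], "p_value": [a[1] for a in assoc]},
            index=[f"PC{i + 1}" for i in range(scores.shape[1])]),
    }
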