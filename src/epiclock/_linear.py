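"""Shared numerical machinery for the site-level and region-level clocks.

Quantile normalization, single-sample rank mapping onto a stored reference
distribution, per-feature standardization, elastic-net regularization paths
(coordinate descent via scikit-learn; exact SVD solution for the pure-ridge
mixing), and the double-loop cross-validation that selects the mixing
parameter (alpha, 1 = lasso, 0 = ridge) and penalty strength (lambda).

The penalized objective matches glmnet's:
    (1/2n) ||y - Xw||^2 + lambda * (alpha ||w||_1 + (1-alpha)/2 ||w||^2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path

__all__ = [
    "quantile_normalize",
    "map_sample_to_reference",
    "standardize",
    "fit_quadratic",
    "CVReport",
    "double_loop_cv",
    "cv_select",
]


# ---------------------------------------------------------------------------
# normalization

def quantile_normalize(frac: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Quantile-normalize columns (samples) of a sites x samples matrix.

    The reference distribution is the mean of per-sample order statistics;
    each sample's values are replaced by the reference values at their
    within-sample ranks, tied values receiving the mean of the tied
    reference values.  Afterwards every sample has an identical sorted
    value vector (the reference).  Missing cells are not allowed.
    """
    X = frac.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing cells: intersect sites before quantile normalization")
    n, k = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the assigned reference values within tied groups
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=frac.index, columns=frac.columns), reference


def map_sample_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one sample's values onto a stored reference distribution.

    Each value's within-sample average rank r (out of m values) is converted
    to the quantile (r - 0.5)/m and the reference's quantile function is
    evaluated there by linear interpolation.  This makes a sample's
    normalized values independent of whatever other samples are processed
    alongside it.
    """
    values = np.asarray(values, dtype=float)
    m = len(values)
    if m == 0:
        raise ValueError("empty sample")
    r = stats.rankdata(values, method="average")
    p = (r - 0.5) / m
    n = len(reference)
    xp = (np.arange(n) + 0.5) / n
    return np.interp(p, xp, reference)


def standardize(mat: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-row (site) z-scoring: mean 0, sample sd 1 (n-1 denominator).

    Raises on zero-variance rows, listing them, so the caller can drop them.
    """
    X = mat.to_numpy(dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=ddof)
    bad = np.where(sds == 0)[0]
    if bad.size:
        names = [str(tuple(mat.index[i])) for i in bad[:10]]
        raise ValueError(f"{bad.size} zero-variance sites (e.g. {names}); drop them before standardizing")
    Z = (X - means[:, None]) / sds[:, None]
    return pd.DataFrame(Z, index=mat.index, columns=mat.columns), means, sds


# ---------------------------------------------------------------------------
# calibration

def fit_quadratic(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares quadratic y ~ a x^2 + b x + c; needs >= 3 distinct x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct raw scores to fit the quadratic calibration")
    a, b, c = np.polyfit(x, y, 2)
    return float(a), float(b), float(c)


# ---------------------------------------------------------------------------
# elastic-net paths and double-loop CV

def _center(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    ym = y.mean()
    return X - xm, y - ym, xm, ym


def lambda_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                n_lambda: int = 40, min_ratio: float | None = None) -> np.ndarray:
    """glmnet-style log-spaced penalty path from the data-driven maximum."""
    Xc, yc, _, _ = _center(X, y)
    n = X.shape[0]
    lam_max = np.abs(Xc.T @ yc).max() / (n * max(l1_ratio, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    if min_ratio is None:
        min_ratio = 1e-4 if l1_ratio < 0.01 else 0.01
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _ridge_path(Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Exact coefficients for the pure-ridge objective at every lambda.

    Objective (1/2n)||y - Xw||^2 + (lambda/2)||w||^2, solved by SVD:
    w = V diag(d / (d^2 + n lambda)) U^T y.  Returns (n_features, n_lambda).
    """
    n = Xc.shape[0]
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ yc
    shrink = d[:, None] / (d[:, None] ** 2 + n * lambdas[None, :])
    return Vt.T @ (shrink * uty[:, None])


def _enet_coef_path(Xc: np.ndarray, yc: np.ndarray, l1_ratio: float,
                    lambdas: np.ndarray) -> np.ndarray:
    """Coefficient path at fixed mixing over a descending lambda grid."""
    if l1_ratio < 1e-6:
        return _ridge_path(Xc, yc, lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(Xc, yc, l1_ratio=l1_ratio, alphas=lambdas,
                                max_iter=2000, tol=1e-4)
    return coefs


def fold_assignment(n: int, n_folds: int, seed: int, strata=None) -> np.ndarray:
    """Seeded fold labels; when strata are given, each stratum is dealt
    round-robin across folds so no fold is confounded with one stratum."""
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if strata is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            folds[chunk] = f
    else:
        strata = np.asarray(strata)
        offset = 0
        for s in pd.unique(strata):
            idx = np.where(strata == s)[0]
            idx = rng.permutation(idx)
            for j, i in enumerate(idx):
                folds[i] = (j + offset) % n_folds
            offset += len(idx)
    return folds


@dataclass
class CVReport:
    """Cross-validation provenance: selections and held-out errors."""

    alpha: float
    lam: float
    inner_mse: float
    outer_mse: list[float] = field(default_factory=list)
    outer_selected: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "lambda": self.lam, "inner_cv_mse": self.inner_mse,
                "outer_heldout_mse": self.outer_mse, "outer_selected": self.outer_selected}


def cv_select(X: np.ndarray, y: np.ndarray, alpha_grid, n_folds: int, seed: int,
              strata=None) -> tuple[float, float, float]:
    """Inner CV: pick (alpha, lambda) minimizing K-fold mean squared error.

    The lambda path per alpha is computed once from the full data (so every
    fold scores the same grid).  Ties break toward larger lambda (stronger
    regularization), then smaller alpha.
    """
    n = X.shape[0]
    if n < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} samples for {n_folds}-fold CV, got {n}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or response")
    folds = fold_assignment(n, n_folds, seed, strata)
    best_key = (np.inf, np.inf, np.inf)
    best = (np.nan, np.nan, np.inf)
    for alpha in alpha_grid:
        lams = lambda_grid(X, y, alpha)
        sse = np.zeros(len(lams))
        cnt = 0
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            if te.sum() == 0 or tr.sum() < 2:
                raise ValueError("fold with too few samples")
            Xc, yc, xm, ym = _center(X[tr], y[tr])
            coefs = _enet_coef_path(Xc, yc, alpha, lams)
            pred = (X[te] - xm) @ coefs + ym
            sse += ((pred - y[te][:, None]) ** 2).sum(axis=0)
            cnt += te.sum()
        mse = sse / cnt
        # ties break toward stronger regularization, then smaller mixing
        for lam, m in zip(lams, mse):
            key = (m, -lam, alpha)
            if key < best_key:
                best_key = key
                best = (float(alpha), float(lam), float(m))
    return best


def fit_at(X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> tuple[np.ndarray, float]:
    """Fit at fixed (alpha, lambda); returns (weights, intercept)."""
    Xc, yc, xm, ym = _center(X, y)
    coefs = _enet_coef_path(Xc, yc, alpha, np.array([lam]))
    w = coefs[:, 0]
    return w, float(ym - xm @ w)


def double_loop_cv(X: np.ndarray, y: np.ndarray, alpha_grid, *, inner_folds: int = 10,
                   outer_folds: int = 10, seed: int = 0, strata=None) -> tuple[np.ndarray, CVReport]:
    """Nested CV: inner folds select (alpha, lambda), outer folds score them.

    The final model is refit on all samples at the (alpha, lambda) chosen by
    an inner CV over the full data.  Returns (weights, report); the report
    carries per-outer-fold selections and held-out MSEs.
    """
    n = X.shape[0]
    outer = fold_assignment(n, outer_folds, seed + 1, strata)
    outer_mse: list[float] = []
    outer_sel: list[tuple[float, float]] = []
    for f in range(outer_folds):
        tr, te = outer != f, outer == f
        strata_tr = None if strata is None else np.asarray(strata)[tr]
        a, l, _ = cv_select(X[tr], y[tr], alpha_grid, inner_folds, seed + 100 + f, strata_tr)
        w, b0 = fit_at(X[tr], y[tr], a, l)
        outer_mse.append(float(np.mean((X[te] @ w + b0 - y[te]) ** 2)))
        outer_sel.append((a, l))
    a, l, inner_mse = cv_select(X, y, alpha_grid, inner_folds, seed, strata)
    w, _ = fit_at(X, y, a, l)
    report = CVReport(alpha=a, lam=l, inner_mse=inner_mse,
                      outer_mse=outer_mse, outer_selected=outer_sel)
    return w, report
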