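"""Lambda selection: per-bootstrap 5-fold CV over a log grid, median over bootstraps.

The procedure mirrors the small-cohort selection scheme: draw B bootstrap
resamples of the patients; within each resample run k-fold cross-validation
over a shared decreasing lambda grid, scoring each lambda by held-out mean
squared error (standardisation parameters are estimated on the training
folds only); take the CV-MSE-minimising lambda of each resample; report the
median across resamples and refit on all data at that median.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from ._kernels import cd_path
from .lasso import LassoFit, PenalizedProblem, lambda_max, lasso_fit

__all__ = [
    "LambdaSearchResult",
    "lambda_grid",
    "cv_mse",
    "bootstrap_median_lambda",
    "final_fit",
]


@dataclass
class LambdaSearchResult:
    per_bootstrap_lambda: np.ndarray
    median_lambda: float
    grid: np.ndarray
    first_bootstrap_curve: np.ndarray | None
    seed: int
    n_redrawn: int = 0
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "median_lambda": self.median_lambda,
            "seed": self.seed,
            "n_bootstraps": int(self.per_bootstrap_lambda.size),
            "n_redrawn": self.n_redrawn,
            "grid": [float(g) for g in self.grid],
            "per_bootstrap_lambda": [float(v) for v in self.per_bootstrap_lambda],
        }


def lambda_grid(lam_max: float, n_points: int = 100, ratio: float = 0.001) -> np.ndarray:
    """Log-spaced, strictly decreasing grid from lam_max down to ratio*lam_max."""
    if lam_max < 0:
        raise ValueError("lambda_max must be non-negative")
    if lam_max == 0:
        warnings.warn("lambda_max is 0; returning the single-point grid {0}")
        return np.zeros(1)
    if n_points < 1:
        raise ValueError("n_points must be positive")
    if n_points == 1:
        return np.array([lam_max])
    return lam_max * ratio ** (np.arange(n_points) / (n_points - 1))


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random partition into k near-equal folds (sizes differ by <=1)."""
    idx = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for f, part in enumerate(np.array_split(idx, k)):
        folds[part] = f
    return folds


def cv_mse(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    k: int = 5,
    seed: int = 0,
    v: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Per-lambda k-fold cross-validated MSE on a raw (unstandardised) design.

    For each fold, centring/scaling of the design and centring of the
    response are computed on the training folds only and applied to the
    held-out fold; the returned curve is the mean over folds of the held-out
    mean squared error at each grid value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError("fewer observations than folds")
    grid = np.asarray(grid, dtype=float)
    if v is None:
        v = np.ones(p)
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, k, rng)
    fold_mse = np.zeros((k, grid.size))
    for f in range(k):
        val = folds == f
        tr = ~val
        if tr.sum() < 2:
            raise ValueError("a training fold has fewer than 2 observations")
        Xt, yt = X[tr], y[tr]
        mean = Xt.mean(axis=0)
        sd = Xt.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
        Xt_s = (Xt - mean) / scale
        ym = yt.mean()
        W = cd_path(Xt_s, yt - ym, v, grid, tol, max_sweeps)
        Xv_s = (X[val] - mean) / scale
        pred = ym + Xv_s @ W.T
        resid = y[val][:, None] - pred
        fold_mse[f] = np.mean(resid**2, axis=0)
    return fold_mse.mean(axis=0)


def bootstrap_median_lambda(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 500,
    k: int = 5,
    seed: int = 0,
    n_grid: int = 100,
    grid_ratio: float = 0.001,
    v: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    max_redraws: int = 100,
    tol: float = 1e-7,
) -> LambdaSearchResult:
    """Median CV-optimal lambda over B patient bootstrap resamples.

    The grid is fixed once from the full-data lambda_max so the per-bootstrap
    optima are comparable; a resample whose response has zero variance is
    redrawn (bounded retries) since CV-MSE is degenerate there. Deterministic
    under ``seed``: each bootstrap consumes one child of a single
    ``SeedSequence(seed)``, in order, for both the resample draw and its fold
    assignment.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if v is None:
        v = np.ones(p)
    full = PenalizedProblem.from_raw(X, y, v=v, feature_names=feature_names)
    grid = lambda_grid(lambda_max(full), n_points=n_grid, ratio=grid_ratio)

    children = np.random.SeedSequence(seed).spawn(B)
    lambdas = np.empty(B)
    first_curve = None
    n_redrawn = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.ptp(yb) > 0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                "bootstrap resample response variance remained zero after retries"
            )
        curve = cv_mse(
            X[idx], yb, grid, k=k, seed=int(rng.integers(2**31)), v=v, tol=tol
        )
        lambdas[b] = grid[int(np.argmin(curve))]
        if b == 0:
            first_curve = curve
    return LambdaSearchResult(
        per_bootstrap_lambda=lambdas,
        median_lambda=float(np.median(lambdas)),
        grid=grid,
        first_bootstrap_curve=first_curve,
        seed=seed,
        n_redrawn=n_redrawn,
        feature_names=full.feature_names,
    )


def final_fit(
    X: np.ndarray,
    y: np.ndarray,
    median_lambda: float,
    v: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    tol: float = 1e-7,
) -> LassoFit:
    """Refit on all observations at the selected lambda (the reported model)."""
    if median_lambda < 0:
        raise ValueError("lambda must be non-negative")
    problem = PenalizedProblem.from_raw(X, y, v=v, feature_names=feature_names)
    fit = lasso_fit(problem, median_lambda, tol=tol)
    if median_lambda >= lambda_max(problem) and np.all(fit.w == 0):
        warnings.warn("selected lambda at or above lambda_max: empty support")
    return fit
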