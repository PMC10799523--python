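"""Weighted-LASSO core: penalised least squares with a per-predictor penalty vector.

The model minimised here is

    Cost(w) = (1/2N) * sum_i (y_i - sum_j w_j x_ij)^2  +  lambda * sum_j v_j |w_j|

where ``v`` is a non-negative per-predictor penalty vector (all ones in the
standard LASSO). The intercept is handled implicitly: the design columns are
centred and scaled and the response is centred, so the unpenalised intercept
equals the raw response mean. Coefficients are reported on the standardised
scale; :func:`coef_raw_scale` maps them back to the raw units.

Binary responses (e.g. 30-day mortality) are fitted with the same
squared-error loss by default — the linear-probability convention — with an
optional logistic-loss variant in :func:`lasso_fit_logistic`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import cd_path, cd_solve

__all__ = [
    "PenalizedProblem",
    "LassoFit",
    "cost",
    "soft_threshold",
    "lambda_max",
    "lasso_fit",
    "lasso_path",
    "kkt_violation",
    "coef_raw_scale",
    "lasso_fit_logistic",
]


@dataclass
class PenalizedProblem:
    """Standardised design/response pair plus the penalty vector.

    ``X`` has centred columns scaled to unit sample variance (n-1
    denominator); raw-constant columns are left at zero after centring and
    carry ``x_scale = 1``. ``y`` is centred; the raw mean is kept as the
    (unpenalised) intercept of any fit.
    """

    X: np.ndarray
    y: np.ndarray
    v: np.ndarray
    feature_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_raw(
        cls,
        X_raw: np.ndarray,
        y_raw: np.ndarray,
        v: np.ndarray | None = None,
        feature_names: list[str] | None = None,
    ) -> "PenalizedProblem":
        X_raw = np.asarray(X_raw, dtype=float)
        y_raw = np.asarray(y_raw, dtype=float)
        if X_raw.ndim != 2:
            raise ValueError("design must be 2-D")
        if y_raw.shape[0] != X_raw.shape[0]:
            raise ValueError("response length does not match design rows")
        if not (np.all(np.isfinite(X_raw)) and np.all(np.isfinite(y_raw))):
            raise ValueError("non-finite values in design or response")
        n, p = X_raw.shape
        mean = X_raw.mean(axis=0)
        sd = X_raw.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
        scale = np.where(sd > 0, sd, 1.0)
        X = (X_raw - mean) / scale
        y_mean = float(y_raw.mean())
        y = y_raw - y_mean
        if v is None:
            v = np.ones(p)
        else:
            v = np.asarray(v, dtype=float)
            if v.shape != (p,):
                raise ValueError("penalty vector length must equal predictor count")
            if np.any(v < 0):
                raise ValueError("penalty vector must be non-negative")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        return cls(X, y, v, list(feature_names), mean, scale, y_mean)


@dataclass
class LassoFit:
    """Solution of the weighted-LASSO problem at a single lambda."""

    w: np.ndarray
    intercept: float
    lam: float
    n_sweeps: int
    converged: bool
    final_cost: float
    feature_names: list[str] = field(default_factory=list)

    @property
    def support(self) -> list[str]:
        return [n for n, w in zip(self.feature_names, self.w) if w != 0.0]

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "intercept": self.intercept,
            "converged": self.converged,
            "n_sweeps": self.n_sweeps,
            "final_cost": self.final_cost,
            "coefficients": {
                n: float(w) for n, w in zip(self.feature_names, self.w)
            },
        }


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ValueError("threshold must be non-negative")
    mag = abs(z) - gamma
    if mag <= 0:
        return 0.0
    return mag if z > 0 else -mag


def cost(problem: PenalizedProblem, w: np.ndarray, lam: float) -> float:
    """Evaluate the penalised cost at coefficients ``w``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    w = np.asarray(w, dtype=float)
    r = problem.y - problem.X @ w
    return float(r @ r / (2 * problem.N) + lam * np.sum(problem.v * np.abs(w)))


def lambda_max(problem: PenalizedProblem) -> float:
    """Smallest lambda at which the solution is identically zero.

    Features with v_j = 0 are never shrunk by the penalty and are excluded;
    if every v_j is zero there is no such lambda.
    """
    mask = problem.v > 0
    if not np.any(mask):
        raise ValueError("all penalty weights are zero; lambda_max undefined")
    corr = np.abs(problem.X.T @ problem.y) / problem.N
    vals = corr[mask] / problem.v[mask]
    return float(np.max(vals)) if vals.size else 0.0


def lasso_fit(
    problem: PenalizedProblem,
    lam: float,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    w0: np.ndarray | None = None,
) -> LassoFit:
    """Solve the weighted LASSO at ``lam`` by cyclic coordinate descent.

    Each coordinate update is the exact one-dimensional minimiser
    ``w_j <- S((1/N) x_j' r_{-j}, lam*v_j) / (x_j' x_j / N)``; the sweep
    stops when the largest coefficient change falls below ``tol``.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    w = np.zeros(problem.p) if w0 is None else np.array(w0, dtype=float)
    n_sweeps, converged = cd_solve(
        problem.X, problem.y, problem.v, float(lam), w, tol, int(max_sweeps)
    )
    return LassoFit(
        w=w,
        intercept=problem.y_mean,
        lam=float(lam),
        n_sweeps=int(n_sweeps),
        converged=bool(converged),
        final_cost=cost(problem, w, lam),
        feature_names=problem.feature_names,
    )


def lasso_path(
    problem: PenalizedProblem,
    grid: np.ndarray,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Warm-started coefficient path over a decreasing lambda grid.

    Returns a (len(grid), p) array; row k is the solution at grid[k].
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be non-increasing for warm starts")
    return cd_path(problem.X, problem.y, problem.v, grid, tol, int(max_sweeps))


def kkt_violation(problem: PenalizedProblem, fit: LassoFit) -> float:
    """Maximum violation of the subgradient optimality conditions.

    At an optimum, (1/N) x_j' r = lam*v_j*sign(w_j) on the support and
    |(1/N) x_j' r| <= lam*v_j off it.
    """
    r = problem.y - problem.X @ fit.w
    g = problem.X.T @ r / problem.N
    bound = fit.lam * problem.v
    off = np.abs(g) - bound
    on = np.abs(g - bound * np.sign(fit.w))
    viol = np.where(fit.w == 0.0, np.maximum(off, 0.0), on)
    return float(np.max(viol)) if viol.size else 0.0


def coef_raw_scale(fit: LassoFit, problem: PenalizedProblem) -> tuple[np.ndarray, float]:
    """Map standardised coefficients back to the raw predictor units.

    Returns (beta_raw, intercept_raw) such that
    y_hat = intercept_raw + X_raw @ beta_raw.
    """
    beta = fit.w / problem.x_scale
    intercept = fit.intercept - float(problem.x_mean @ beta)
    return beta, intercept


def lasso_fit_logistic(
    problem: PenalizedProblem,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 20_000,
) -> LassoFit:
    """L1-penalised logistic regression variant (optional, non-default).

    Minimises (1/N) * sum_i log(1 + exp(-(2y_i-1) * (b + x_i'w)))
    + lam * sum_j v_j |w_j| for a 0/1 response by proximal gradient (ISTA
    with backtracking). The response is taken from ``problem.y`` plus its
    stored mean (i.e. the raw 0/1 labels).
    """
    y01 = problem.y + problem.y_mean
    if not np.all(np.isin(y01.round(12), [0.0, 1.0])):
        raise ValueError("logistic variant requires a 0/1 response")
    s = 2.0 * y01 - 1.0
    X = problem.X
    N, p = X.shape
    w = np.zeros(p)
    b = 0.0

    def nll(w, b):
        eta = b + X @ w
        return float(np.mean(np.logaddexp(0.0, -s * eta)))

    # Lipschitz bound for the logistic gradient: ||X||^2 / (4N)
    L = max(np.linalg.norm(X, 2) ** 2 / (4 * N), 1e-12) + 0.25
    step = 1.0 / L
    thr = lam * problem.v * step
    prev = np.inf
    it = 0
    for it in range(max_iter):
        eta = b + X @ w
        sig = 1.0 / (1.0 + np.exp(-eta))
        grad_w = X.T @ (sig - y01) / N
        grad_b = float(np.mean(sig - y01))
        w_new = np.sign(w - step * grad_w) * np.maximum(
            np.abs(w - step * grad_w) - thr, 0.0
        )
        b_new = b - step * grad_b
        delta = max(np.max(np.abs(w_new - w)), abs(b_new - b))
        w, b = w_new, b_new
        obj = nll(w, b) + lam * float(problem.v @ np.abs(w))
        if delta < tol and prev - obj < tol:
            break
        prev = obj
    return LassoFit(
        w=w,
        intercept=b,
        lam=float(lam),
        n_sweeps=it + 1,
        converged=it + 1 < max_iter,
        final_cost=nll(w, b) + lam * float(problem.v @ np.abs(w)),
        feature_names=problem.feature_names,
    )
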