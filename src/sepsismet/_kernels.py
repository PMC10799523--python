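"""Numba kernels for the weighted-LASSO coordinate descent solver.

Kept separate so the pure-Python API surface in :mod:`sepsismet.lasso`
stays readable and the kernels can be cached/compiled once per process.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cd_solve(X, y, v, lam, w, tol, max_sweeps):  # pragma: no cover - compiled
    """Cyclic coordinate descent on (1/2N)||y - Xw||^2 + lam * sum_j v_j |w_j|.

    Mutates ``w`` in place (warm start). Columns need not be exactly
    unit-norm: the update divides by x_j^T x_j / N, so the solver is exact
    for any column scaling. Returns (n_sweeps, converged).
    """
    N, p = X.shape
    cn = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(N):
            s += X[i, j] * X[i, j]
        cn[j] = s / N
    r = y - X @ w
    n_sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if cn[j] == 0.0:
                continue
            wj = w[j]
            s = 0.0
            for i in range(N):
                s += X[i, j] * r[i]
            # (1/N) x_j^T r_{-j} where r_{-j} excludes feature j's contribution
            rho = s / N + wj * cn[j]
            z = abs(rho) - lam * v[j]
            if z <= 0.0:
                wnew = 0.0
            else:
                wnew = z / cn[j] if rho > 0.0 else -z / cn[j]
            d = wnew - wj
            if d != 0.0:
                for i in range(N):
                    r[i] -= d * X[i, j]
                w[j] = wnew
                if abs(d) > max_delta:
                    max_delta = abs(d)
        n_sweeps = sweep + 1
        if max_delta < tol:
            converged = True
            break
    return n_sweeps, converged


@njit(cache=True)
def cd_path(X, y, v, grid, tol, max_sweeps):  # pragma: no cover - compiled
    """Warm-started solution path over a decreasing lambda grid.

    Returns a (len(grid), p) coefficient matrix; row k solves the problem at
    ``grid[k]`` warm-started from row k-1.
    """
    p = X.shape[1]
    W = np.zeros((grid.shape[0], p))
    w = np.zeros(p)
    for k in range(grid.shape[0]):
        cd_solve(X, y, v, grid[k], w, tol, max_sweeps)
        W[k, :] = w
    return W
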