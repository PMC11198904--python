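"""Gram-matrix elastic-net coordinate descent along a regularization path.

Feature selection in this package only needs the *support* of the elastic-net
solution at a sequence of penalty strengths.  The path is computed by cyclic
coordinate descent on the Gram matrix (p x p), which makes the per-call cost
independent of sample count after the Gram product and keeps the many
thousands of selection calls made by the null/permutation machinery cheap.
Coefficients agree with :func:`sklearn.linear_model.enet_path` at matched
penalties (asserted in the test suite); sklearn is the reference, not a
dependency of this routine.

Objective (sklearn parameterization, X and y given via Q = X'X, q = X'y):

    1/(2n) ||y - Xw||^2 + alpha * l1_ratio * ||w||_1
                        + alpha * (1 - l1_ratio)/2 * ||w||^2
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enet_support_path", "enet_alpha_grid"]


@njit(cache=True)
def _cd_path(Q, q, n, alphas, l1_ratio, tol, max_iter, support_stop):
    p = Q.shape[0]
    n_alphas = alphas.shape[0]
    coefs = np.zeros((p, n_alphas))
    w = np.zeros(p)
    c = q.copy()  # c = q - Q w, maintained incrementally
    n_done = 0
    for ai in range(n_alphas):
        l1 = n * alphas[ai] * l1_ratio
        l2 = n * alphas[ai] * (1.0 - l1_ratio)
        for _ in range(max_iter):
            d_max = 0.0
            for j in range(p):
                wj = w[j]
                rho = c[j] + Q[j, j] * wj
                if rho > l1:
                    wn = (rho - l1) / (Q[j, j] + l2)
                elif rho < -l1:
                    wn = (rho + l1) / (Q[j, j] + l2)
                else:
                    wn = 0.0
                d = wn - wj
                if d != 0.0:
                    w[j] = wn
                    for k in range(p):
                        c[k] -= Q[k, j] * d
                    if abs(d) > d_max:
                        d_max = abs(d)
            if d_max < tol:
                break
        coefs[:, ai] = w
        n_done = ai + 1
        nnz = 0
        for j in range(p):
            if w[j] != 0.0:
                nnz += 1
        if nnz >= support_stop:
            break
    return coefs[:, :n_done]


def enet_alpha_grid(q: np.ndarray, n: int, l1_ratio: float,
                    n_alphas: int, eps: float) -> np.ndarray:
    """Geometric penalty grid from the smallest alpha with empty support."""
    alpha_max = float(np.max(np.abs(q))) / (n * l1_ratio)
    if alpha_max <= 0.0:
        alpha_max = 1.0
    return alpha_max * np.geomspace(1.0, eps, n_alphas)


def enet_support_path(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    n_alphas: int = 100,
    eps: float = 1e-3,
    tol: float = 1e-5,
    max_iter: int = 1000,
    support_stop: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients along a geometric penalty path.

    Parameters
    ----------
    X : (n, p) array, predictors in columns (centered/standardized upstream).
    y : (n,) response.
    support_stop : stop the path early once the support reaches this size;
        points past it cannot be closest to any smaller target support.
        ``None`` computes the full path.

    Returns
    -------
    alphas : (k,) penalties actually visited (k <= n_alphas).
    coefs : (p, k) coefficients; column j solves the problem at alphas[j].
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = X.shape[0]
    Q = X.T @ X
    q = X.T @ y
    alphas = enet_alpha_grid(q, n, l1_ratio, n_alphas, eps)
    stop = X.shape[1] + 1 if support_stop is None else support_stop
    coefs = _cd_path(Q, q, n, alphas, l1_ratio, tol, max_iter, stop)
    return alphas[: coefs.shape[1]], coefs
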