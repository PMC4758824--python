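"""Soft-margin SVM dual solver for precomputed kernels.

Sequential minimal optimization (SMO) with maximal-violating-pair working
set selection, compiled with numba.  The solver is deliberately small and
warm-startable: the multiple-kernel optimizer calls it thousands of times
on kernels that change only slightly between line-search steps.

Dual problem (labels y in {-1, +1}, kernel K, box 0 <= alpha <= C)::

    max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij
    s.t.       0 <= alpha_i <= C,   sum_i alpha_i y_i = 0
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _smo(K, y, C, alpha, G, tol, max_iter):  # pragma: no cover - jitted
    """In-place SMO on (alpha, G); G must equal y*(K@(alpha*y)) - 1 on entry.

    Returns (n_iter, kkt_gap).  G is the gradient of the minimization form
    ``1/2 a^T Q a - e^T a`` with ``Q_ij = y_i y_j K_ij``.
    """
    n = K.shape[0]
    it = 0
    gap = 0.0
    # bound membership uses a relative tolerance: values within eps_b of a
    # bound are treated as AT the bound, or the working-set selection can
    # pick a pair that moves by ~1e-17 and stall
    eps_b = 1e-10 * C
    hi = C - eps_b
    while it < max_iter:
        i = -1
        j = -1
        gmax = -1e300
        gmin = 1e300
        for t in range(n):
            yg = -y[t] * G[t]
            if (y[t] > 0 and alpha[t] < hi) or (y[t] < 0 and alpha[t] > eps_b):
                if yg > gmax:
                    gmax = yg
                    i = t
            if (y[t] > 0 and alpha[t] > eps_b) or (y[t] < 0 and alpha[t] < hi):
                if yg < gmin:
                    gmin = yg
                    j = t
        gap = gmax - gmin
        if gap < tol or i < 0 or j < 0:
            break
        yi, yj = y[i], y[j]
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 1e-12:
            quad = 1e-12
        delta = (-yi * G[i] + yj * G[j]) / quad
        old_ai = alpha[i]
        old_aj = alpha[j]
        s = yi * old_ai + yj * old_aj
        ai = old_ai + yi * delta
        if ai < 0.0:
            ai = 0.0
        elif ai > C:
            ai = C
        aj = yj * (s - yi * ai)
        if aj < 0.0:
            aj = 0.0
            ai = yi * (s - yj * aj)
        elif aj > C:
            aj = C
            ai = yi * (s - yj * aj)
        if ai < 0.0:
            ai = 0.0
        elif ai > C:
            ai = C
        dai = ai - old_ai
        daj = aj - old_aj
        if abs(dai) < 1e-16 and abs(daj) < 1e-16:
            break
        for t in range(n):
            G[t] += y[t] * (yi * K[t, i] * dai + yj * K[t, j] * daj)
        alpha[i] = ai
        alpha[j] = aj
        it += 1
    return it, gap


def solve_warm(K: np.ndarray, y: np.ndarray, C: float,
               alpha0: np.ndarray | None = None,
               tol: float = 1e-8, max_iter: int = 200000,
               ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Solve the dual, optionally warm-starting from a feasible ``alpha0``.

    Returns ``(alpha, G, objective, n_iter)`` where G is the final
    gradient of the minimization form (used for warm restarts and the
    bias).
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = K.shape[0]
    if alpha0 is None or not np.any(alpha0):
        alpha = np.zeros(n)
        G = -np.ones(n)
    else:
        alpha = np.clip(np.ascontiguousarray(alpha0, dtype=np.float64), 0.0, C)
        # snap float leftovers onto the bounds exactly
        alpha[alpha > C * (1.0 - 1e-10)] = C
        alpha[alpha < C * 1e-10] = 0.0
        G = y * (K @ (alpha * y)) - 1.0
    n_iter, _ = _smo(K, y, C, alpha, G, tol, max_iter)
    # objective from the gradient: alpha^T G = alpha^T Q alpha - sum(alpha)
    obj = 0.5 * (alpha.sum() - alpha @ G)
    return alpha, G, float(obj), n_iter


def bias_from_gradient(y: np.ndarray, C: float, alpha: np.ndarray,
                       G: np.ndarray) -> float:
    """Bias of the decision function, averaged over free support vectors.

    For a free SV (0 < alpha < C), ``y_i (s_i + b) = 1`` with
    ``s_i = sum_j alpha_j y_j K_ij``; ``-y_i G_i = y_i - s_i`` gives b
    directly.  Without free SVs the midpoint of the KKT interval is used.
    """
    yg = -y * G  # equals y_i - s_i
    free = (alpha > 1e-10 * max(C, 1.0)) & (alpha < C * (1 - 1e-10))
    if np.any(free):
        return float(yg[free].mean())
    up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
    low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
    hi = yg[up].max() if np.any(up) else 0.0
    lo = yg[low].min() if np.any(low) else 0.0
    return float((hi + lo) / 2.0)


def svm_dual_solve(K: np.ndarray, y: np.ndarray, C: float,
                   tol: float = 1e-8, max_iter: int = 200000,
                   ) -> tuple[np.ndarray, float, float]:
    """Solve the SVM dual on a precomputed kernel.

    Parameters
    ----------
    K
        Symmetric positive semi-definite ``(n, n)`` kernel.
    y
        Labels in {-1, +1}; both classes must be present.
    C
        Soft-margin parameter, > 0.

    Returns
    -------
    alpha, b, objective
        Dual coefficients, bias and dual objective value.
    """
    K = np.asarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8 * (np.abs(K).max() + 1.0)):
        raise ValueError("K must be symmetric")
    if len(np.unique(np.sign(y))) < 2:
        raise ValueError("both classes must be present")
    if C <= 0:
        raise ValueError("C must be positive")
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8 * max(np.trace(K) / K.shape[0], 1.0):
        raise ValueError("K is not positive semi-definite within tolerance")
    alpha, G, obj, _ = solve_warm(K, y, C, tol=tol, max_iter=max_iter)
    b = bias_from_gradient(y, C, alpha, G)
    return alpha, b, obj
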