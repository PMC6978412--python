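"""Coordinate-descent path solver for non-negative elastic-net logistic
regression on binary features.

The fit minimizes (glmnet scaling)

    (1/n) sum_i [log(1 + exp(eta_i)) - y_i eta_i]
        + lam * (alpha * sum_j b_j + (1-alpha)/2 * sum_j b_j^2),  b_j >= 0,

by iteratively reweighted least squares with cyclic coordinate descent on
each quadratic approximation, warm-started along a descending lambda path.
Columns are binary presence indicators, so each coordinate update only
touches the rows where the feature is present (CSC-style index arrays).
After a full sweep, inner iterations cycle over the active (non-zero) set
until convergence, then one more full sweep checks optimality.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enet_path_binary"]

_W_FLOOR = 1e-5


@njit(cache=False)
def _cd_quadratic(indptr, indices, y_len, w, res, beta, b0, lam, alpha, xv, tol, max_inner):
    """CD sweeps on one weighted quadratic approximation.

    ``res`` holds w*(z - eta) = y - p at entry and is kept consistent with
    coefficient updates.  Returns the updated intercept.
    """
    p = xv.shape[0]
    wsum = 0.0
    for i in range(y_len):
        wsum += w[i]
    active = np.zeros(p, dtype=np.uint8)
    full_sweep = True
    for _ in range(max_inner):
        maxdel = 0.0
        # intercept (unpenalized, unconstrained)
        d0 = 0.0
        for i in range(y_len):
            d0 += res[i]
        d0 /= wsum
        if d0 != 0.0:
            b0 += d0
            for i in range(y_len):
                res[i] -= d0 * w[i]
            ad = abs(d0) * np.sqrt(wsum / y_len)
            if ad > maxdel:
                maxdel = ad
        for j in range(p):
            if not full_sweep and active[j] == 0:
                continue
            den = xv[j] + lam * (1.0 - alpha)
            if den <= 0.0:
                continue
            g = 0.0
            for k in range(indptr[j], indptr[j + 1]):
                g += res[indices[k]]
            g = g / y_len + beta[j] * xv[j]
            bn = (g - lam * alpha) / den
            if bn < 0.0:
                bn = 0.0
            d = bn - beta[j]
            if d != 0.0:
                beta[j] = bn
                for k in range(indptr[j], indptr[j + 1]):
                    i = indices[k]
                    res[i] -= d * w[i]
                ad = abs(d) * np.sqrt(xv[j]) if xv[j] > 0 else abs(d)
                if ad > maxdel:
                    maxdel = ad
            active[j] = 1 if beta[j] != 0.0 else 0
        if maxdel < tol:
            if full_sweep:
                break
            full_sweep = True  # converged on active set: verify with full sweep
        else:
            full_sweep = False
    return b0


@njit(cache=False)
def _enet_path_kernel(indptr, indices, y, lambdas, alpha, tol, max_outer, max_inner):
    n = y.shape[0]
    p = indptr.shape[0] - 1
    L = lambdas.shape[0]
    out = np.zeros((L, p + 1))
    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    xv = np.empty(p)
    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_outer):
            pr = np.empty(n)
            w = np.empty(n)
            res = np.empty(n)
            for i in range(n):
                e = eta[i]
                pi = 1.0 / (1.0 + np.exp(-e))
                wi = pi * (1.0 - pi)
                if wi < _W_FLOOR:
                    wi = _W_FLOOR
                pr[i] = pi
                w[i] = wi
                res[i] = y[i] - pi
            for j in range(p):
                s = 0.0
                for k in range(indptr[j], indptr[j + 1]):
                    s += w[indices[k]]
                xv[j] = s / n
            b0 = _cd_quadratic(
                indptr, indices, n, w, res, beta, b0, lam, alpha, xv, tol, max_inner
            )
            # rebuild eta; outer loop converges when probabilities stop moving
            for i in range(n):
                eta[i] = b0
            for j in range(p):
                bj = beta[j]
                if bj != 0.0:
                    for k in range(indptr[j], indptr[j + 1]):
                        eta[indices[k]] += bj
            de = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                dd = abs(pi - pr[i])
                if dd > de:
                    de = dd
            if de < 1e-7:
                break
        out[li, 0] = b0
        for j in range(p):
            out[li, j + 1] = beta[j]
    return out


def enet_path_binary(
    X,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float = 1e-7,
    max_outer: int = 12,
    max_inner: int = 500,
) -> np.ndarray:
    """Warm-started coefficient path; rows of the result are
    [intercept, b_1..b_p] per lambda.

    ``X`` may be a dense 0/1 array or any scipy sparse matrix with binary
    entries.
    """
    import scipy.sparse as sp

    Xc = sp.csc_matrix(X)
    indptr = Xc.indptr.astype(np.int64)
    indices = Xc.indices.astype(np.int64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    return _enet_path_kernel(
        indptr, indices, y, lambdas, float(alpha), tol, max_outer, max_inner
    )
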