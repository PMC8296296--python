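"""Numba-compiled core for the covariance-form FFBS recursions.

Identical algorithm to the pure-numpy path in :mod:`tvpvarsv._ffbs` — forward
Kalman filter with per-step symmetrization, Carter-Kohn backward sampling
with escalating diagonal jitter (1e-10, 1e-8, 1e-6) on Cholesky failure —
compiled once per process.  The small-matrix Cholesky and triangular solves
are hand-written loops: at state dimensions below ~10 they beat LAPACK
dispatch overhead and sidestep exception handling inside compiled code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ffbs_core"]

_OK, _FAIL = 0, 1


@njit(cache=True)
def _cholesky(S, L):
    """Lower Cholesky of S into L; returns 0 on success, 1 on failure."""
    k = S.shape[0]
    for i in range(k):
        for j in range(i + 1):
            acc = S[i, j]
            for p in range(j):
                acc -= L[i, p] * L[j, p]
            if i == j:
                if acc <= 0.0:
                    return _FAIL
                L[i, i] = np.sqrt(acc)
            else:
                L[i, j] = acc / L[j, j]
        for j in range(i + 1, k):
            L[i, j] = 0.0
    return _OK


@njit(cache=True)
def _cholesky_jitter(S, L):
    """Cholesky with escalating diagonal jitter; returns the status flag."""
    if _cholesky(S, L) == _OK:
        return _OK
    for bump in (1e-10, 1e-8, 1e-6):
        Sj = S.copy()
        for i in range(S.shape[0]):
            Sj[i, i] += bump
        if _cholesky(Sj, L) == _OK:
            return _OK
    return _FAIL


@njit(cache=True)
def _chol_solve(L, B, X):
    """Solve (L L^T) X = B for X given lower-triangular L."""
    k, ncol = B.shape
    for c in range(ncol):
        for i in range(k):  # forward: L w = b
            acc = B[i, c]
            for p in range(i):
                acc -= L[i, p] * X[p, c]
            X[i, c] = acc / L[i, i]
        for i in range(k - 1, -1, -1):  # backward: L^T x = w
            acc = X[i, c]
            for p in range(i + 1, k):
                acc -= L[p, i] * X[p, c]
            X[i, c] = acc / L[i, i]


@njit(cache=True)
def ffbs_core(y, Z, H, q, a1, p1, z, sample):
    """Forward filter + backward pass.  Returns (path, status).

    y (n,p); Z (n,p,k); H (n,p,p); q (k,) state innovation variances;
    a1, p1 (k,) initial mean/variance diagonal; z (n,k) standard normals
    (ignored when sample is False).
    """
    n, p = y.shape
    k = Z.shape[2]
    a = a1.copy()
    P = np.zeros((k, k))
    for i in range(k):
        P[i, i] = p1[i]
    a_f = np.empty((n, k))
    P_f = np.empty((n, k, k))
    Lp = np.empty((p, p))
    Lk = np.empty((k, k))
    out = np.empty((n, k))

    for t in range(n):
        if t > 0:
            for i in range(k):
                P[i, i] += q[i]
        Zt = Z[t]
        PZ = P @ Zt.T                       # (k, p)
        F = Zt @ PZ + H[t]                  # (p, p)
        if _cholesky_jitter(F, Lp) == _FAIL:
            return out, _FAIL
        KT = np.empty((p, k))
        _chol_solve(Lp, PZ.T.copy(), KT)    # F KT = PZ^T  ->  K = KT^T
        v = y[t] - Zt @ a
        a = a + KT.T @ v
        P = P - KT.T @ (Zt @ P)
        P = 0.5 * (P + P.T)
        a_f[t] = a
        P_f[t] = P.copy()

    if sample:
        if _cholesky_jitter(P_f[n - 1], Lk) == _FAIL:
            return out, _FAIL
        out[n - 1] = a_f[n - 1] + Lk @ z[n - 1]
    else:
        out[n - 1] = a_f[n - 1]
    for t in range(n - 2, -1, -1):
        Pt = P_f[t]
        S = Pt.copy()
        for i in range(k):
            S[i, i] += q[i]
        if _cholesky_jitter(S, Lk) == _FAIL:
            return out, _FAIL
        GT = np.empty((k, k))
        _chol_solve(Lk, Pt.copy(), GT)      # (Pt+Q) GT = Pt  ->  G = GT^T
        mean = a_f[t] + GT.T @ (out[t + 1] - a_f[t])
        if sample:
            C = Pt - GT.T @ Pt
            C = 0.5 * (C + C.T)
            if _cholesky_jitter(C, Lk) == _FAIL:
                return out, _FAIL
            out[t] = mean + Lk @ z[t]
        else:
            out[t] = mean
    return out, _OK
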