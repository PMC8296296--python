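"""Forward-filtering backward-sampling for random-walk linear-Gaussian models.

All three Gibbs blocks of the sampler reduce to the same state space

    y_t = Z_t theta_t + eps_t,     eps_t ~ N(0, H_t)
    theta_{t+1} = theta_t + eta_t, eta_t ~ N(0, diag(q))
    theta_1 ~ N(a1, diag(p1))

so one covariance-form Kalman filter serves them all.  ``sample=True`` draws
an exact path from p(theta_{1:n} | y_{1:n}) (Carter-Kohn backward pass);
``sample=False`` returns the smoother means (Rauch-Tung-Striebel), which the
test oracles compare against a dense joint-Gaussian solve.

Filter covariances are symmetrized every step; a Cholesky failure during the
backward pass triggers escalating diagonal jitter starting at 1e-10 (a
persistent failure signals numerical misuse and raises).
"""

from __future__ import annotations

import numpy as np

try:  # compiled fast path; the numpy recursions below are the fallback
    from ._ffbs_fast import ffbs_core as _ffbs_core
except ImportError:  # pragma: no cover
    _ffbs_core = None

__all__ = ["kalman_ffbs", "kalman_ffbs_univariate"]


class FilterError(FloatingPointError):
    """Filter or sampling covariance lost positive definiteness."""


def _chol_with_jitter(S: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    for bump in (0.0, jitter, jitter * 1e2, jitter * 1e4):
        try:
            return np.linalg.cholesky(S + bump * np.eye(S.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise FilterError("covariance not positive definite even after jitter")


def kalman_ffbs(
    y: np.ndarray,
    Z: np.ndarray,
    H: np.ndarray,
    q: np.ndarray,
    a1: np.ndarray,
    p1: np.ndarray,
    rng: np.random.Generator | None = None,
    sample: bool = True,
) -> np.ndarray:
    """FFBS for a k-dimensional random-walk state observed through Z_t.

    Parameters
    ----------
    y : (n, p) observations.
    Z : (n, p, k) observation designs.
    H : (n, p, p) full or (n, p) diagonal observation noise covariances.
    q : (k,) state innovation variances (diagonal).
    a1, p1 : (k,) initial state mean and variance diagonal.
    sample : draw a path if True, else return smoother means.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, p = y.shape
    Z = np.ascontiguousarray(np.asarray(Z, dtype=float).reshape(n, p, -1))
    k = Z.shape[2]
    q = np.ascontiguousarray(np.broadcast_to(np.asarray(q, dtype=float).ravel(), (k,)))
    H = np.asarray(H, dtype=float)
    diag_H = H.ndim == 2
    a1_vec = np.ascontiguousarray(
        np.broadcast_to(np.asarray(a1, dtype=float).ravel(), (k,))
    )
    p1_vec = np.ascontiguousarray(
        np.broadcast_to(np.asarray(p1, dtype=float).ravel(), (k,))
    )

    if sample and rng is None:
        raise ValueError("rng required when sample=True")
    z = rng.standard_normal((n, k)) if sample else np.zeros((n, k))

    if _ffbs_core is not None:
        H_full = np.ascontiguousarray(
            np.einsum("np,pq->npq", H, np.eye(p)) if diag_H else H
        )
        out, status = _ffbs_core(
            np.ascontiguousarray(y), Z, H_full, q, a1_vec, p1_vec, z, sample
        )
        if status != 0:
            raise FilterError("covariance not positive definite even after jitter")
        return out

    a = a1_vec.copy()
    P = np.diag(p1_vec)
    Q = np.diag(q)
    I_k = np.eye(k)

    a_filt = np.empty((n, k))
    P_filt = np.empty((n, k, k))
    for t in range(n):
        if t > 0:
            P = P + Q  # random-walk prediction; mean unchanged
        Zt = Z[t]
        PZ = P @ Zt.T                                    # (k, p)
        F = Zt @ PZ                                      # (p, p)
        if diag_H:
            F[np.diag_indices(p)] += H[t]
        else:
            F = F + H[t]
        v = y[t] - Zt @ a
        K = np.linalg.solve(F, PZ.T).T                   # (k, p) gain
        a = a + K @ v
        P = (I_k - K @ Zt) @ P
        P = 0.5 * (P + P.T)
        a_filt[t] = a
        P_filt[t] = P

    out = np.empty((n, k))
    if sample:
        L = _chol_with_jitter(P_filt[n - 1])
        out[n - 1] = a_filt[n - 1] + L @ z[n - 1]
        for t in range(n - 2, -1, -1):
            Pt = P_filt[t]
            G = np.linalg.solve(Pt + Q, Pt).T            # Pt (Pt+Q)^{-1}
            mean = a_filt[t] + G @ (out[t + 1] - a_filt[t])
            cov = Pt - G @ Pt
            cov = 0.5 * (cov + cov.T)
            L = _chol_with_jitter(cov)
            out[t] = mean + L @ z[t]
    else:
        out[n - 1] = a_filt[n - 1]
        for t in range(n - 2, -1, -1):
            Pt = P_filt[t]
            G = np.linalg.solve(Pt + Q, Pt).T
            out[t] = a_filt[t] + G @ (out[t + 1] - a_filt[t])
    return out


def kalman_ffbs_univariate(
    y: np.ndarray,
    obs_var: np.ndarray,
    q: float,
    a1: float,
    p1: float,
    rng: np.random.Generator | None = None,
    sample: bool = True,
) -> np.ndarray:
    """Scalar-state FFBS (identity observation), used by the volatility block.

    Plain-float inner loop: at these lengths the scalar recursions dominate
    the sampler's cost, so avoiding array overhead matters.
    """
    y = np.asarray(y, dtype=float).ravel()
    obs_var = np.asarray(obs_var, dtype=float).ravel()
    n = y.size
    a, P = float(a1), float(p1)
    q = float(q)
    a_f = np.empty(n)
    P_f = np.empty(n)
    yl = y.tolist()
    vl = obs_var.tolist()
    for t in range(n):
        if t > 0:
            P += q
        F = P + vl[t]
        K = P / F
        a = a + K * (yl[t] - a)
        P = P - K * P
        a_f[t] = a
        P_f[t] = P

    out = np.empty(n)
    if sample:
        if rng is None:
            raise ValueError("rng required when sample=True")
        z = rng.standard_normal(n)
        out[n - 1] = a_f[n - 1] + np.sqrt(max(P_f[n - 1], 0.0)) * z[n - 1]
        prev = out[n - 1]
        for t in range(n - 2, -1, -1):
            Pt = P_f[t]
            G = Pt / (Pt + q)
            mean = a_f[t] + G * (prev - a_f[t])
            var = Pt - G * Pt
            prev = mean + np.sqrt(max(var, 0.0)) * z[t]
            out[t] = prev
    else:
        out[n - 1] = a_f[n - 1]
        prev = out[n - 1]
        for t in range(n - 2, -1, -1):
            Pt = P_f[t]
            G = Pt / (Pt + q)
            prev = a_f[t] + G * (prev - a_f[t])
            out[t] = prev
    return out
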