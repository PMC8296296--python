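"""Model definition for the time-varying-parameter VAR with stochastic volatility.

The structural system is

    A_t y_t = M_1 y_{t-1} + ... + M_s y_{t-s} + u_t,       u_t ~ N(0, Sigma_t^2)

with A_t unit-lower-triangular (recursive identification) and
Sigma_t = diag(sigma_1t, ..., sigma_mt).  Writing B_i = A_t^{-1} M_i and
stacking all reduced-form coefficients into beta_t gives the observation
equation

    y_t = X_t beta_t + A_t^{-1} Sigma_t eps_t,   eps_t ~ N(0, I_m),
    X_t = I_m  (kron)  (y'_{t-1}, ..., y'_{t-s})

and the latent states beta_t (coefficients), alpha_t (free lower-triangular
entries of A_t, row-major) and h_t (log-variances, h_jt = ln sigma_jt^2) all
follow first-order random walks with diagonal innovation covariances.

This module holds the model algebra: the Kronecker design, the alpha <-> A_t
mapping, the per-observation Gaussian log-likelihood, the reduced-form solve
B_i = A^{-1} M_i and the companion-matrix stability check.  Sampling lives in
:mod:`tvpvarsv.mcmc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "ModelSpec",
    "StatePaths",
    "InnovationVariances",
    "PriorConfig",
    "VARCoefficients",
    "build_design",
    "alpha_to_A",
    "extract_alpha",
    "loglik_obs",
    "reduced_form",
    "beta_to_B",
    "spectral_radius",
    "spectral_radius_path",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Dimensions and variable ordering of the VAR.

    ``names`` fixes both m and the recursive-identification ordering: a
    variable's structural shock may move contemporaneously only the variables
    ordered after it.  The default ordering for the study system is
    (new, pas, pek): epidemic counts first, mobility second, PM2.5 last.
    """

    names: tuple[str, ...] = ("new", "pas", "pek")
    lag: int = 1
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.m < 1 or self.lag < 1:
            raise ValueError("need m >= 1 and lag >= 1")
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def m(self) -> int:
        return len(self.names)

    @property
    def k_beta(self) -> int:
        per_eq = self.m * self.lag + (1 if self.include_intercept else 0)
        return self.m * per_eq

    @property
    def k_alpha(self) -> int:
        return self.m * (self.m - 1) // 2

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "m": self.m,
            "s": self.lag,
            "include_intercept": self.include_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            names=tuple(d["names"]),
            lag=int(d.get("s", d.get("lag", 1))),
            include_intercept=bool(d.get("include_intercept", False)),
        )


@dataclass
class StatePaths:
    """Latent state paths over the effective sample t = s+1..T (T-s rows)."""

    beta: np.ndarray   # (n, k_beta)
    alpha: np.ndarray  # (n, k_alpha)
    h: np.ndarray      # (n, m)

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(self.beta.shape[0], -1)
        self.h = np.atleast_2d(np.asarray(self.h, dtype=float))
        n = self.beta.shape[0]
        if self.alpha.shape[0] != n or self.h.shape[0] != n:
            raise ValueError("state paths must share their row count")
        for arr, label in ((self.beta, "beta"), (self.alpha, "alpha"), (self.h, "h")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {label} path")

    @property
    def n_times(self) -> int:
        return self.beta.shape[0]

    def copy(self) -> "StatePaths":
        return StatePaths(self.beta.copy(), self.alpha.copy(), self.h.copy())


@dataclass
class InnovationVariances:
    """Diagonal state-innovation variances for the three random-walk blocks."""

    v_beta: np.ndarray
    v_alpha: np.ndarray
    v_h: np.ndarray

    def __post_init__(self) -> None:
        self.v_beta = np.asarray(self.v_beta, dtype=float).ravel()
        self.v_alpha = np.asarray(self.v_alpha, dtype=float).ravel()
        self.v_h = np.asarray(self.v_h, dtype=float).ravel()
        for arr, label in ((self.v_beta, "v_beta"), (self.v_alpha, "v_alpha"), (self.v_h, "v_h")):
            if arr.size and not np.all(arr > 0):
                raise ValueError(f"{label} must be strictly positive")


@dataclass(frozen=True)
class PriorConfig:
    """Priors on initial states and on innovation precisions.

    Initial states: beta_{s+1} ~ N(0, 10 I), alpha_{s+1} ~ N(0, 10 I),
    h_{s+1} ~ N(0, 100 I).  Each diagonal innovation scale has a Gamma prior
    on its inverse square (shape-rate convention): shape 40, rate 0.02 for
    the coefficient block and shape 4, rate 0.02 for the alpha and h blocks.
    """

    beta0_mean: float = 0.0
    alpha0_mean: float = 0.0
    h0_mean: float = 0.0
    beta0_var: float = 10.0
    alpha0_var: float = 10.0
    h0_var: float = 100.0
    gamma_beta_shape: float = 40.0
    gamma_beta_rate: float = 0.02
    gamma_alpha_shape: float = 4.0
    gamma_alpha_rate: float = 0.02
    gamma_h_shape: float = 4.0
    gamma_h_rate: float = 0.02

    def __post_init__(self) -> None:
        for f in ("beta0_var", "alpha0_var", "h0_var",
                  "gamma_beta_shape", "gamma_beta_rate",
                  "gamma_alpha_shape", "gamma_alpha_rate",
                  "gamma_h_shape", "gamma_h_rate"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in (
            "beta0_mean", "alpha0_mean", "h0_mean",
            "beta0_var", "alpha0_var", "h0_var",
            "gamma_beta_shape", "gamma_beta_rate",
            "gamma_alpha_shape", "gamma_alpha_rate",
            "gamma_h_shape", "gamma_h_rate")}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# model algebra
# ---------------------------------------------------------------------------


def build_design(values: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Kronecker design stack: X_t = I_m kron (y'_{t-1}, ..., y'_{t-s}).

    ``values`` is the full T x m adjusted panel; the result is an
    (T-s, m, k_beta) array, one m x k_beta design per effective observation
    t = s+1..T (a leading 1 is prepended to the lag stack when the spec
    includes an intercept).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    T, m = values.shape
    s = spec.lag
    if m != spec.m:
        raise ValueError(f"panel has {m} variables, spec expects {spec.m}")
    if T <= s:
        raise ValueError(f"need more than s={s} observations, got {T}")
    n = T - s
    per_eq = m * s + (1 if spec.include_intercept else 0)
    x = np.empty((n, per_eq))
    col = 0
    if spec.include_intercept:
        x[:, 0] = 1.0
        col = 1
    for lag in range(1, s + 1):
        x[:, col:col + m] = values[s - lag:T - lag, :]
        col += m
    X = np.zeros((n, m, m * per_eq))
    for i in range(m):
        X[:, i, i * per_eq:(i + 1) * per_eq] = x
    return X


def alpha_to_A(alpha_vec: np.ndarray, m: int) -> np.ndarray:
    """Unit-lower-triangular A from the row-major stack of its strict lower entries."""
    alpha_vec = np.asarray(alpha_vec, dtype=float).ravel()
    k = m * (m - 1) // 2
    if alpha_vec.size != k:
        raise ValueError(f"alpha has length {alpha_vec.size}, expected {k}")
    A = np.eye(m)
    idx = np.tril_indices(m, k=-1)
    A[idx] = alpha_vec
    return A


def extract_alpha(A: np.ndarray) -> np.ndarray:
    """Inverse of :func:`alpha_to_A`: row-major strict lower triangle of A."""
    A = np.asarray(A, dtype=float)
    return A[np.tril_indices(A.shape[0], k=-1)].copy()


def loglik_obs(
    y_t: np.ndarray,
    X_t: np.ndarray,
    beta_t: np.ndarray,
    alpha_t: np.ndarray,
    h_t: np.ndarray,
) -> float:
    """Log density of one observation under N(X_t beta_t, A^{-1} S^2 A^{-T}).

    With r = y_t - X_t beta_t, u = A_t r is the structural residual and the
    quadratic form reduces to sum_j (u_j^2 exp(-h_jt)); det(A_t) = 1 so the
    log determinant of the covariance is just sum_j h_jt.
    """
    y_t = np.asarray(y_t, dtype=float).ravel()
    h_t = np.asarray(h_t, dtype=float).ravel()
    m = y_t.size
    X_t = np.asarray(X_t, dtype=float).reshape(m, -1)
    beta_t = np.asarray(beta_t, dtype=float).ravel()
    if not (np.all(np.isfinite(beta_t)) and np.all(np.isfinite(h_t))):
        raise ValueError("non-finite states")
    r = y_t - X_t @ beta_t
    u = alpha_to_A(alpha_t, m) @ r
    return float(-0.5 * (m * LOG_2PI + h_t.sum() + np.sum(u * u * np.exp(-h_t))))


def reduced_form(A: np.ndarray, M_list: list[np.ndarray]) -> list[np.ndarray]:
    """Reduced-form lag matrices B_i = A^{-1} M_i by exact triangular solve."""
    A = np.asarray(A, dtype=float)
    assert np.allclose(np.diag(A), 1.0), "A must be unit-lower-triangular"
    return [solve_triangular(A, np.asarray(M, dtype=float), lower=True) for M in M_list]


def beta_to_B(beta_t: np.ndarray, spec: ModelSpec) -> list[np.ndarray]:
    """Unstack beta_t into reduced-form lag matrices B_1..B_s (intercept dropped)."""
    m, s = spec.m, spec.lag
    per_eq = m * s + (1 if spec.include_intercept else 0)
    mat = np.asarray(beta_t, dtype=float).reshape(m, per_eq)
    off = 1 if spec.include_intercept else 0
    return [mat[:, off + (l - 1) * m: off + l * m].copy() for l in range(1, s + 1)]


@dataclass
class VARCoefficients:
    """One date's structural/reduced-form coefficient set.

    Invariants: A unit-lower-triangular, B_i = A^{-1} M_i exactly,
    Sigma = diag(sigma_j) with sigma_j = exp(h_j / 2).
    """

    A: np.ndarray
    M: list[np.ndarray] = field(default_factory=list)
    B: list[np.ndarray] = field(default_factory=list)
    sigma: np.ndarray = field(default_factory=lambda: np.array([]))

    @classmethod
    def from_states(
        cls, beta_t: np.ndarray, alpha_t: np.ndarray, h_t: np.ndarray, spec: ModelSpec
    ) -> "VARCoefficients":
        A = alpha_to_A(alpha_t, spec.m)
        B = beta_to_B(beta_t, spec)
        M = [A @ Bi for Bi in B]
        return cls(A=A, M=M, B=B, sigma=np.exp(np.asarray(h_t, dtype=float) / 2.0))


def spectral_radius(beta_t: np.ndarray, spec: ModelSpec) -> float:
    """Largest eigenvalue modulus of the companion matrix of B_1..B_s."""
    B = beta_to_B(beta_t, spec)
    m, s = spec.m, spec.lag
    C = np.zeros((m * s, m * s))
    for i, Bi in enumerate(B):
        C[:m, i * m:(i + 1) * m] = Bi
    if s > 1:
        C[m:, :-m] = np.eye(m * (s - 1))
    return float(np.max(np.abs(np.linalg.eigvals(C))))


def spectral_radius_path(beta_path: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Companion spectral radius at every date of a coefficient path (batched)."""
    beta_path = np.atleast_2d(np.asarray(beta_path, dtype=float))
    n = beta_path.shape[0]
    m, s = spec.m, spec.lag
    per_eq = m * s + (1 if spec.include_intercept else 0)
    mats = beta_path.reshape(n, m, per_eq)
    off = 1 if spec.include_intercept else 0
    C = np.zeros((n, m * s, m * s))
    for l in range(s):
        C[:, :m, l * m:(l + 1) * m] = mats[:, :, off + l * m: off + (l + 1) * m]
    if s > 1:
        C[:, m:, :-m] = np.eye(m * (s - 1))
    return np.max(np.abs(np.linalg.eigvals(C)), axis=1)
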