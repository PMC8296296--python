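"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tvpvarsv import ModelSpec, StatePaths, simulate_tvpvar
from tvpvarsv.preprocess import AdjustedPanel


def dense_rw_smoother_mean(y, Z, H, q, a1, p1):
    """Posterior mean of a random-walk state path by one dense Gaussian solve.

    Independent oracle for the FFBS recursions: stack all n states into a
    single nk-dimensional Gaussian, accumulate the precision contributions of
    the initial prior, the random-walk transitions and every observation, and
    solve.  O((nk)^3) — only usable on tiny instances, which is the point.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, p = y.shape
    Z = np.asarray(Z, dtype=float).reshape(n, p, -1)
    k = Z.shape[2]
    H = np.asarray(H, dtype=float)
    if H.ndim == 2:  # diagonal shorthand
        H = np.stack([np.diag(H[t]) for t in range(n)])
    Qinv = np.diag(1.0 / np.asarray(q, dtype=float))
    Lam = np.zeros((n * k, n * k))
    rhs = np.zeros(n * k)
    P1inv = np.diag(1.0 / np.broadcast_to(np.asarray(p1, float).ravel(), (k,)))
    a1 = np.broadcast_to(np.asarray(a1, float).ravel(), (k,))
    Lam[:k, :k] += P1inv
    rhs[:k] += P1inv @ a1
    for t in range(n - 1):
        sl0 = slice(t * k, (t + 1) * k)
        sl1 = slice((t + 1) * k, (t + 2) * k)
        Lam[sl0, sl0] += Qinv
        Lam[sl1, sl1] += Qinv
        Lam[sl0, sl1] -= Qinv
        Lam[sl1, sl0] -= Qinv
    for t in range(n):
        sl = slice(t * k, (t + 1) * k)
        Hinv = np.linalg.inv(H[t])
        Lam[sl, sl] += Z[t].T @ Hinv @ Z[t]
        rhs[t * k:(t + 1) * k] += Z[t].T @ Hinv @ y[t]
    return np.linalg.solve(Lam, rhs).reshape(n, k)


def constant_parameter_panel(seed: int, T: int = 300):
    """m=2 panel drawn from a time-invariant, homoskedastic parameterization."""
    spec = ModelSpec(names=("x1", "x2"), lag=1)
    beta0 = np.array([0.5, 0.1, 0.2, 0.4])  # B = [[.5,.1],[.2,.4]], stable
    init = StatePaths(beta0[None, :], np.array([[0.3]]), np.zeros((1, 2)))
    panel, truth = simulate_tvpvar(spec, init, (0.0, 0.0, 0.0), T, seed=seed)
    adjusted = AdjustedPanel(panel.dates, panel.values, panel.names)
    return spec, adjusted, truth


@pytest.fixture(scope="session")
def study_panel():
    from tvpvarsv import StudyScenarioConfig, make_study_like_panel

    return make_study_like_panel(StudyScenarioConfig(seed=7))
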