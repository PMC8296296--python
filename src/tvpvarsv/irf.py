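"""Time-varying impulse responses and the two reporting modes.

At each date t the posterior supplies a coefficient set (B_1..B_s from
beta_t, A_t from alpha_t, volatilities from h_t).  Holding those parameters
fixed over the horizon, the moving-average coefficients are

    psi_0 = A_t^{-1} diag(shock_scale),
    psi_k = sum_{i=1..min(k,s)} B_i psi_{k-i},

so psi_k[i, j] is the horizon-k response of variable i to a one-standard-
deviation structural shock in variable j.  Under the recursive ordering,
variables ordered before the shocked one do not move at horizon 0.

Two summaries mirror the usual presentation for this model family:
equal-interval slices (response at fixed horizons — 1 day, 1 week, 2 weeks —
traced over calendar dates) and time-point slices (the full horizon curve at
selected dates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ModelSpec
from .mcmc import PosteriorDraws

__all__ = ["IRFSurface", "irf_at", "tv_irf", "equal_interval_slices",
           "timepoint_slices"]

MAX_HORIZON = 120  # memory guard for the surface computation


@dataclass
class IRFSurface:
    """Posterior-summary impulse responses over (date, horizon, shock, response)."""

    dates: pd.DatetimeIndex
    horizons: np.ndarray                # 0..H
    mean: np.ndarray                    # (n_dates, H+1, m, m): [t, k, i, j]
    names: tuple[str, ...]
    shock_convention: str
    lower: np.ndarray | None = None     # 16% band, same shape as mean
    upper: np.ndarray | None = None     # 84% band

    @property
    def H(self) -> int:
        return int(self.horizons[-1])

    def _pair(self, shock: str, response: str) -> tuple[int, int]:
        try:
            return self.names.index(response), self.names.index(shock)
        except ValueError as exc:
            raise KeyError(f"unknown variable in pair ({shock!r}, {response!r}); "
                           f"panel variables are {self.names}") from exc

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: date, horizon, shock, response, value[, bands]."""
        n, H1, m, _ = self.mean.shape
        recs = {
            "date": np.repeat(self.dates.strftime("%Y-%m-%d"), H1 * m * m),
            "horizon": np.tile(np.repeat(self.horizons, m * m), n),
            "response": np.tile(np.repeat(list(self.names), m), n * H1),
            "shock": np.tile(list(self.names), n * H1 * m),
            "value": self.mean.ravel(),
        }
        if self.lower is not None:
            recs["lower"] = self.lower.ravel()
            recs["upper"] = self.upper.ravel()
        return pd.DataFrame(recs)


def irf_at(
    beta_t: np.ndarray,
    alpha_t: np.ndarray,
    shock_scale: np.ndarray | float,
    spec: ModelSpec,
    H: int,
) -> np.ndarray:
    """Impulse responses for one date's coefficient set, horizons 0..H."""
    if H < 0:
        raise ValueError("H must be non-negative")
    m, s = spec.m, spec.lag
    beta_t = np.asarray(beta_t, dtype=float).ravel()
    if not np.all(np.isfinite(beta_t)):
        raise ValueError("non-finite coefficient states")
    scale = np.broadcast_to(np.asarray(shock_scale, dtype=float), (m,))
    from .core import alpha_to_A, beta_to_B

    B = beta_to_B(beta_t, spec)
    A = alpha_to_A(alpha_t, m)
    psi = np.empty((H + 1, m, m))
    # A^{-1} diag(scale) is exactly lower triangular; scrub solver dust
    psi[0] = np.tril(np.linalg.solve(A, np.diag(scale)))
    for k in range(1, H + 1):
        acc = np.zeros((m, m))
        for i in range(1, min(k, s) + 1):
            acc += B[i - 1] @ psi[k - i]
        psi[k] = acc
    return psi


def _beta_stack_to_B(beta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """(R, k_beta) -> (s, R, m, m) reduced-form lag matrices."""
    R = beta.shape[0]
    m, s = spec.m, spec.lag
    per_eq = m * s + (1 if spec.include_intercept else 0)
    off = 1 if spec.include_intercept else 0
    mats = beta.reshape(R, m, per_eq)
    return np.stack([mats[:, :, off + l * m: off + (l + 1) * m] for l in range(s)])


def tv_irf(
    draws: PosteriorDraws,
    spec: ModelSpec | None = None,
    H: int = 14,
    convention: str = "average_volatility",
    compute_bands: bool = False,
    band: tuple[float, float] = (0.16, 0.84),
) -> IRFSurface:
    """Posterior impulse-response surface, averaged over retained draws.

    ``convention`` fixes the one-standard-deviation shock size: with
    ``average_volatility`` each series' scale is that draw's time-average of
    exp(h_jt / 2), making responses comparable across dates; ``time_t``
    uses the date-specific exp(h_jt / 2).
    """
    if draws.n_retained == 0:
        raise ValueError("no retained draws")
    if H > MAX_HORIZON:
        raise ValueError(f"H={H} exceeds the configured cap {MAX_HORIZON}")
    if convention not in ("average_volatility", "time_t"):
        raise ValueError("convention must be 'average_volatility' or 'time_t'")
    spec = spec or draws.spec
    m, s = spec.m, spec.lag
    R, n = draws.n_retained, draws.n_times

    idx = np.tril_indices(m, k=-1)
    A = np.broadcast_to(np.eye(m), (R, m, m)).copy()
    B_all = _beta_stack_to_B(draws.beta.reshape(R * n, -1), spec).reshape(s, R, n, m, m)
    avg_scale = np.exp(draws.h / 2.0).mean(axis=1)  # (R, m) per-draw time-average

    mean = np.empty((n, H + 1, m, m))
    lower = np.empty_like(mean) if compute_bands else None
    upper = np.empty_like(mean) if compute_bands else None
    for t in range(n):
        A[:, idx[0], idx[1]] = draws.alpha[:, t, :]
        A_inv = np.tril(np.linalg.inv(A))  # exactly lower triangular in theory
        scale = avg_scale if convention == "average_volatility" \
            else np.exp(draws.h[:, t, :] / 2.0)
        psi = np.empty((H + 1, R, m, m))
        psi[0] = A_inv * scale[:, None, :]
        Bt = B_all[:, :, t]  # (s, R, m, m)
        for k in range(1, H + 1):
            acc = Bt[0] @ psi[k - 1]
            for i in range(2, min(k, s) + 1):
                acc += Bt[i - 1] @ psi[k - i]
            psi[k] = acc
        mean[t] = psi.mean(axis=1)
        if compute_bands:
            q = np.quantile(psi, band, axis=1)
            lower[t], upper[t] = q[0], q[1]

    dates = pd.DatetimeIndex(draws.dates) if draws.dates is not None \
        else pd.DatetimeIndex(pd.RangeIndex(n).map(lambda i: pd.Timestamp(2000, 1, 1) + pd.Timedelta(days=i)))
    return IRFSurface(dates=dates, horizons=np.arange(H + 1), mean=mean,
                      names=spec.names, shock_convention=convention,
                      lower=lower, upper=upper)


def equal_interval_slices(
    surface: IRFSurface,
    shock: str,
    response: str,
    horizons: tuple[int, ...] = (1, 7, 14),
) -> pd.DataFrame:
    """Per-date response trajectories at fixed horizons (short/mid/long term)."""
    for hz in horizons:
        if hz not in surface.horizons:
            raise ValueError(f"horizon {hz} not computed (surface has 0..{surface.H})")
    i, j = surface._pair(shock, response)
    data = {"date": surface.dates}
    for hz in horizons:
        data[f"h{hz}"] = surface.mean[:, hz, i, j]
    return pd.DataFrame(data).set_index("date")


def timepoint_slices(
    surface: IRFSurface,
    shock: str,
    response: str,
    dates: tuple[str, ...] = ("2020-01-22", "2020-03-30", "2020-06-17"),
) -> pd.DataFrame:
    """Full horizon-response curves at selected calendar dates."""
    i, j = surface._pair(shock, response)
    out = {"horizon": surface.horizons}
    valid = (surface.dates[0].date(), surface.dates[-1].date())
    for d in dates:
        ts = pd.Timestamp(d)
        pos = surface.dates.get_indexer([ts])
        if pos[0] == -1:
            raise ValueError(f"date {d} outside the surface range {valid[0]}..{valid[1]}")
        out[str(ts.date())] = surface.mean[pos[0], :, i, j]
    return pd.DataFrame(out).set_index("horizon")
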