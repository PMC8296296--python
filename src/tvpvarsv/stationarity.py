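"""Augmented Dickey-Fuller screening of the adjusted series.

Each series entering the VAR is tested for a unit root under the three
standard deterministic-term specifications — no deterministic terms, a
constant ("drift"), and constant plus linear trend.  The augmentation order
is capped by Schwert's rule, floor(12 * (T/100)^(1/4)), and chosen by AIC
below that cap unless a fixed lag is requested.

The test regression

    dy_t = rho * y_{t-1} + sum_i phi_i dy_{t-i} + deterministic + e_t

is estimated by OLS; the statistic is the t-ratio on rho.  P-values and
1/5/10% critical values come from the MacKinnon response surfaces (via
statsmodels' tabulations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.adfvalues import mackinnoncrit, mackinnonp

__all__ = ["ADFSpec", "ADFResult", "schwert_max_lag", "adf_test", "adf_table",
           "DETERMINISTIC_SPECS"]

# Mapping of the reporting labels to the standard regression codes:
# "without constant and drift" -> none, "with drift" -> constant,
# "with constant and drift" -> constant + linear trend.
DETERMINISTIC_SPECS = ("none", "constant", "constant+trend")
_REGRESSION_CODE = {"none": "n", "constant": "c", "constant+trend": "ct"}


@dataclass(frozen=True)
class ADFSpec:
    """Deterministic terms, lag cap and lag-selection rule for one ADF test."""

    deterministic: str = "constant"
    max_lag: int | None = None  # None -> Schwert rule
    lag_rule: str = "aic"       # "aic" or "fixed" (fixed uses max_lag exactly)

    def __post_init__(self) -> None:
        if self.deterministic not in DETERMINISTIC_SPECS:
            raise ValueError(f"deterministic must be one of {DETERMINISTIC_SPECS}")
        if self.lag_rule not in ("aic", "fixed"):
            raise ValueError("lag_rule must be 'aic' or 'fixed'")
        if self.max_lag is not None and self.max_lag < 0:
            raise ValueError("max_lag must be non-negative")


@dataclass
class ADFResult:
    statistic: float
    pvalue: float
    chosen_lag: int
    deterministic: str
    critical_values: dict[str, float]  # keys "1%", "5%", "10%"

    @property
    def reject(self) -> dict[str, bool]:
        """Unit-root rejection flags at the 1/5/10% levels."""
        return {lvl: self.statistic < cv for lvl, cv in self.critical_values.items()}

    @property
    def stars(self) -> str:
        if self.pvalue < 0.01:
            return "***"
        if self.pvalue < 0.05:
            return "**"
        if self.pvalue < 0.10:
            return "*"
        return ""


def schwert_max_lag(T: int) -> int:
    """Schwert's augmentation-lag cap, floor(12 * (T/100)^(1/4))."""
    if T < 25:
        raise ValueError(f"need T >= 25, got {T}")
    return int(np.floor(12.0 * (T / 100.0) ** 0.25))


def _adf_regression(y: np.ndarray, lag: int, deterministic: str, start: int):
    """OLS of the ADF regression using observations from index ``start`` on.

    Returns (t-ratio on the lagged level, log-likelihood, n_params, nobs).
    ``start`` >= lag + 1 fixes a common effective sample across candidate
    lags so that AIC comparisons are valid.
    """
    dy = np.diff(y)
    nobs = dy.size - start + 1  # dy indices start-1 .. end
    lhs = dy[start - 1:]
    cols = [y[start - 1:-1]]
    for i in range(1, lag + 1):
        cols.append(dy[start - 1 - i: dy.size - i])
    if deterministic in ("constant", "constant+trend"):
        cols.append(np.ones(nobs))
    if deterministic == "constant+trend":
        cols.append(np.arange(start, start + nobs, dtype=float))
    Xmat = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(Xmat, lhs, rcond=None)
    resid = lhs - Xmat @ coef
    ssr = float(resid @ resid)
    dof = nobs - Xmat.shape[1]
    if dof <= 0 or ssr <= 0:
        raise ValueError("degenerate ADF regression (constant series?)")
    sigma2 = ssr / dof
    XtX_inv = np.linalg.inv(Xmat.T @ Xmat)
    tstat = coef[0] / np.sqrt(sigma2 * XtX_inv[0, 0])
    llf = -0.5 * nobs * (np.log(2 * np.pi) + np.log(ssr / nobs) + 1.0)
    return float(tstat), float(llf), Xmat.shape[1], nobs


def adf_test(series: np.ndarray | pd.Series, spec: ADFSpec = ADFSpec()) -> ADFResult:
    """ADF unit-root test of one complete series under the given spec."""
    y = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be complete and finite")
    T = y.size
    max_lag = spec.max_lag if spec.max_lag is not None else schwert_max_lag(T)
    if max_lag >= T / 2:
        raise ValueError(f"max_lag {max_lag} too large for series of length {T}")
    if T <= 2 * max_lag + 10:
        raise ValueError(f"series too short (T={T}) for max_lag={max_lag}")
    if np.ptp(y) == 0:
        raise ValueError("constant series has no unit-root test")

    if spec.lag_rule == "fixed":
        chosen = max_lag
        tstat, _, _, _ = _adf_regression(y, chosen, spec.deterministic, chosen + 1)
    else:
        # common start index so every candidate uses the same sample (AIC-valid)
        start = max_lag + 1
        best = None
        for lag in range(0, max_lag + 1):
            tstat_l, llf, kparams, _ = _adf_regression(y, lag, spec.deterministic, start)
            aic = -2.0 * llf + 2.0 * kparams
            if best is None or aic < best[0]:
                best = (aic, lag, tstat_l)
        _, chosen, _ = best
        # re-estimate at the chosen lag on its maximal sample
        tstat, _, _, _ = _adf_regression(y, chosen, spec.deterministic, chosen + 1)

    code = _REGRESSION_CODE[spec.deterministic]
    nobs_used = T - chosen - 1
    pvalue = float(mackinnonp(tstat, regression=code, N=1))
    crit = mackinnoncrit(N=1, regression=code, nobs=nobs_used)
    return ADFResult(
        statistic=tstat,
        pvalue=pvalue,
        chosen_lag=chosen,
        deterministic=spec.deterministic,
        critical_values={"1%": float(crit[0]), "5%": float(crit[1]),
                         "10%": float(crit[2])},
    )


def adf_table(panel, max_lag: int | None = None, lag_rule: str = "aic") -> pd.DataFrame:
    """Run all three deterministic specs on every panel variable.

    Returns a table shaped like the usual reporting layout: one row per
    variable, one "statistic + stars" column per deterministic spec.
    """
    frame = panel.to_frame()
    rows = []
    for name in frame.columns:
        row: dict[str, object] = {"Variables": name}
        for det, label in zip(
            DETERMINISTIC_SPECS,
            ("Without Constant and Drift", "With Drift", "With Constant and Drift"),
        ):
            res = adf_test(frame[name].to_numpy(),
                           ADFSpec(deterministic=det, max_lag=max_lag, lag_rule=lag_rule))
            row[label] = f"{res.statistic:.3f} {res.stars}".strip()
        rows.append(row)
    return pd.DataFrame(rows)
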