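"""Raw daily panels to model-ready series.

The raw inputs are a daily multivariate panel (epidemic counts, subway
passenger flow, daily-mean PM2.5) with sporadic missingness, plus a table of
previous-year monthly means used for seasonal adjustment.  This module turns
that into the complete, seasonally adjusted panel the time-varying VAR
consumes:

1. multiple imputation of missing cells (chained equations with Bayesian
   linear regression on calendar covariates and the other series),
2. seasonal adjustment by subtracting the previous year's mean for the same
   calendar month from each daily value,
3. descriptive statistics (N, mean, min, max, sample SD) per series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DailySeriesPanel",
    "MonthlyBaseline",
    "AdjustedPanel",
    "DescriptiveStats",
    "read_panel",
    "write_panel",
    "read_baseline",
    "write_baseline",
    "impute_missing",
    "ImputationResult",
    "seasonal_adjust",
    "describe",
]


class PanelError(ValueError):
    """Malformed or inconsistent panel data."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DailySeriesPanel:
    """Dated m-variate daily observations with an explicit missingness mask.

    ``values`` is a T x m float array holding NaN wherever ``missing_mask`` is
    True; dates are consecutive calendar days (validated).
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    missing_mask: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.names = tuple(self.names)
        T, m = self.values.shape
        if len(self.dates) != T or self.missing_mask.shape != (T, m):
            raise PanelError("dates, values and missing_mask shapes disagree")
        if len(self.names) != m:
            raise PanelError(f"{len(self.names)} names for {m} columns")
        _check_consecutive(self.dates)
        # NaN and mask must agree cell-wise
        self.values = np.where(self.missing_mask, np.nan, self.values)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_vars(self) -> int:
        return len(self.names)

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dates, columns=list(self.names))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DailySeriesPanel":
        values = frame.to_numpy(dtype=float)
        return cls(
            dates=pd.DatetimeIndex(frame.index),
            values=values,
            missing_mask=np.isnan(values),
            names=tuple(frame.columns),
        )


@dataclass
class MonthlyBaseline:
    """Previous-year mean level per (variable, calendar month).

    Every month 1..12 must be present for every variable; a variable with no
    previous-year analogue (epidemic counts in the year before the outbreak)
    carries an all-zero baseline.
    """

    means: pd.DataFrame  # columns: variable, month, mean

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.means, columns=["variable", "month", "mean"]).copy()
        df["month"] = df["month"].astype(int)
        df["mean"] = df["mean"].astype(float)
        for var, grp in df.groupby("variable"):
            months = set(grp["month"])
            missing = sorted(set(range(1, 13)) - months)
            if missing:
                raise PanelError(f"baseline for {var!r} lacks months {missing}")
        self.means = df.sort_values(["variable", "month"]).reset_index(drop=True)

    def lookup(self, variable: str, month: int) -> float:
        sel = self.means[(self.means["variable"] == variable) & (self.means["month"] == month)]
        if sel.empty:
            raise PanelError(f"no baseline for variable {variable!r}, month {month}")
        return float(sel["mean"].iloc[0])

    @classmethod
    def from_dict(cls, by_variable: dict[str, np.ndarray | list | float]) -> "MonthlyBaseline":
        """Build from ``{variable: 12 monthly means}`` (scalar broadcasts)."""
        rows = []
        for var, means in by_variable.items():
            arr = np.broadcast_to(np.asarray(means, dtype=float), (12,))
            for month, mu in zip(range(1, 13), arr):
                rows.append({"variable": var, "month": month, "mean": float(mu)})
        return cls(pd.DataFrame(rows))


@dataclass
class AdjustedPanel:
    """Complete, seasonally adjusted panel: value = raw − baseline(month)."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.names = tuple(self.names)
        if not np.all(np.isfinite(self.values)):
            raise PanelError("adjusted panel must be complete and finite")
        if self.values.shape != (len(self.dates), len(self.names)):
            raise PanelError("adjusted panel shape mismatch")
        _check_consecutive(self.dates)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dates, columns=list(self.names))


@dataclass
class DescriptiveStats:
    """Per-variable N, mean, min, max and sample standard deviation."""

    table: pd.DataFrame  # index: variable; columns: N, Mean, Min, Max, Std. Dev.

    def to_csv(self, path: str | Path) -> None:
        out = self.table.reset_index().rename(columns={"index": "Variables"})
        out.to_csv(path, index=False)


def _check_consecutive(dates: pd.DatetimeIndex) -> None:
    if len(dates) == 0:
        raise PanelError("empty date index")
    if dates.has_duplicates or not dates.is_monotonic_increasing:
        raise PanelError("dates must be strictly increasing")
    deltas = np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int)
    gaps = np.nonzero(deltas != 1)[0]
    if gaps.size:
        i = gaps[0]
        raise PanelError(
            f"calendar gap between {dates[i].date()} and {dates[i + 1].date()}"
        )


# ---------------------------------------------------------------------------
# CSV I/O   (panel: date,new,pas,pek with empty cell = missing;
#            baseline: variable,month,mean)
# ---------------------------------------------------------------------------


def write_panel(panel: DailySeriesPanel, path: str | Path) -> None:
    df = panel.to_frame().copy()
    df.insert(0, "date", panel.dates.strftime("%Y-%m-%d"))
    df.to_csv(path, index=False)


def read_panel(path: str | Path) -> DailySeriesPanel:
    """Read a daily panel CSV written by :func:`write_panel`.

    Rejects malformed dates and non-consecutive calendars, naming the gap.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "date" not in df.columns:
        raise PanelError(f"{path}: missing 'date' column")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="%Y-%m-%d"))
    except (ValueError, TypeError) as exc:
        raise PanelError(f"{path}: malformed date ({exc})") from exc
    names = tuple(c for c in df.columns if c != "date")
    values = df[list(names)].to_numpy(dtype=float)
    return DailySeriesPanel(dates, values, np.isnan(values), names)


def write_baseline(baseline: MonthlyBaseline, path: str | Path) -> None:
    baseline.means.to_csv(path, index=False)


def read_baseline(path: str | Path) -> MonthlyBaseline:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return MonthlyBaseline(pd.read_csv(path))


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------


@dataclass
class ImputationResult:
    """Completed copies of a panel plus their cell-wise mean."""

    completed: list[DailySeriesPanel]
    consensus: DailySeriesPanel


def _calendar_features(dates: pd.DatetimeIndex) -> np.ndarray:
    """Calendar covariates for the chained-equation regressions.

    Day index, day-of-week indicators, month indicators, plus a smooth
    local-in-time basis (Gaussian bumps spaced 10 days, width 7) so the
    regressions can track sub-monthly level changes — epidemic waves and
    mobility suppression move faster than the month indicators can follow.
    All columns are complete by construction.
    """
    T = len(dates)
    t = np.arange(T, dtype=float)
    cols = [t / max(T - 1, 1)]
    for k in range(6):
        cols.append(np.asarray(dates.dayofweek == k, dtype=float))
    months = sorted(dates.month.unique())
    for mo in months[1:]:
        cols.append(np.asarray(dates.month == mo, dtype=float))
    for center in np.arange(0.0, T + 1e-9, 10.0):
        cols.append(np.exp(-0.5 * ((t - center) / 7.0) ** 2))
    return np.column_stack(cols)


def impute_missing(
    panel: DailySeriesPanel, n_imputations: int = 5, seed: int = 0
) -> ImputationResult:
    """Multiple imputation of missing cells by chained equations.

    Each variable is regressed (Bayesian linear regression, posterior
    sampling) on calendar covariates — day index, day-of-week and month
    indicators — and the other variables' same-day values, iterated for 10
    sweeps.  ``n_imputations`` independently seeded completed copies are
    returned together with their cell-wise mean (the consensus panel the
    downstream model consumes).  Observed cells are never altered.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge

    if n_imputations < 1:
        raise ValueError("n_imputations must be >= 1")
    frac_obs = 1.0 - panel.missing_mask.mean(axis=0)
    for name, f in zip(panel.names, frac_obs):
        if f == 0.0:
            raise PanelError(f"variable {name!r} is fully missing")
        if f < 0.5:
            raise PanelError(f"variable {name!r} has under 50% observed cells")

    feats = _calendar_features(panel.dates)
    m = panel.n_vars
    # z-score the value columns on their observed cells so one shared ridge
    # prior treats all series and the 0/1 calendar indicators comparably
    loc = np.array([panel.values[~panel.missing_mask[:, j], j].mean()
                    for j in range(m)])
    scl = np.array([panel.values[~panel.missing_mask[:, j], j].std()
                    for j in range(m)])
    scl[scl == 0] = 1.0
    X_full = np.hstack([(panel.values - loc) / scl, feats])

    child_seeds = np.random.SeedSequence(seed).generate_state(n_imputations) % (2**31 - 1)
    completed: list[DailySeriesPanel] = []
    for rs in child_seeds:
        if panel.is_complete:
            filled = panel.values.copy()
        else:
            imp = IterativeImputer(
                estimator=BayesianRidge(),
                sample_posterior=True,
                max_iter=10,
                random_state=int(rs),
                skip_complete=True,
            )
            filled = imp.fit_transform(X_full)[:, :m] * scl + loc
            filled = np.where(panel.missing_mask, filled, panel.values)
        completed.append(
            DailySeriesPanel(panel.dates, filled, np.zeros_like(panel.missing_mask), panel.names)
        )
    consensus_values = np.mean([p.values for p in completed], axis=0)
    consensus = DailySeriesPanel(
        panel.dates, consensus_values, np.zeros_like(panel.missing_mask), panel.names
    )
    return ImputationResult(completed, consensus)


# ---------------------------------------------------------------------------
# seasonal adjustment and descriptives
# ---------------------------------------------------------------------------


def seasonal_adjust(panel: DailySeriesPanel, baseline: MonthlyBaseline) -> AdjustedPanel:
    """Subtract each variable's previous-year monthly mean from its daily values."""
    if not panel.is_complete:
        raise PanelError("panel must be imputed (complete) before adjustment")
    base = np.empty_like(panel.values)
    months = panel.dates.month.to_numpy()
    for j, name in enumerate(panel.names):
        per_month = np.array([baseline.lookup(name, mo) for mo in range(1, 13)])
        base[:, j] = per_month[months - 1]
    return AdjustedPanel(panel.dates, panel.values - base, panel.names)


def describe(panel: DailySeriesPanel | AdjustedPanel) -> DescriptiveStats:
    """N, mean, min, max and sample SD per variable, Table-style."""
    values = panel.values
    if values.size == 0:
        raise PanelError("empty panel")
    if isinstance(panel, DailySeriesPanel) and not panel.is_complete:
        raise PanelError("describe requires a complete panel")
    table = pd.DataFrame(
        {
            "N": np.full(len(panel.names), values.shape[0], dtype=int),
            "Mean": values.mean(axis=0),
            "Min": values.min(axis=0),
            "Max": values.max(axis=0),
            "Std. Dev.": values.std(axis=0, ddof=1),
        },
        index=list(panel.names),
    )
    return DescriptiveStats(table)
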