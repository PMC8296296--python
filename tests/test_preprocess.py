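"""Imputation, seasonal adjustment, descriptives and panel CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from tvpvarsv import (
    DailySeriesPanel,
    MonthlyBaseline,
    StudyScenarioConfig,
    describe,
    impute_missing,
    inject_missing,
    make_study_like_panel,
    read_panel,
    seasonal_adjust,
    write_panel,
)
from tvpvarsv.preprocess import PanelError, read_baseline, write_baseline


def _panel(values, start="2020-01-01", names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    names = names or tuple(f"v{i}" for i in range(values.shape[1]))
    dates = pd.date_range(start, periods=values.shape[0], freq="D")
    return DailySeriesPanel(dates, values, np.isnan(values), names)


class TestPanelIO:
    def test_write_read_write_round_trip_is_byte_identical(self, tmp_path, study_panel):
        panel, _ = study_panel
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_panel(panel, p1)
        write_panel(read_panel(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_study_like_file_has_242_rows(self, tmp_path, study_panel):
        panel, _ = study_panel
        path = tmp_path / "p.csv"
        write_panel(panel, path)
        assert read_panel(path).n_days == 242

    def test_calendar_gap_is_rejected_and_named(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("date,x\n2020-01-01,1\n2020-01-02,2\n2020-01-04,3\n")
        with pytest.raises(PanelError, match="2020-01-02.*2020-01-04"):
            read_panel(path)

    def test_malformed_date_is_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,x\n2020-01-01,1\nnot-a-date,2\n")
        with pytest.raises(PanelError, match="malformed date"):
            read_panel(path)

    def test_baseline_round_trip(self, tmp_path, study_panel):
        _, baseline = study_panel
        path = tmp_path / "b.csv"
        write_baseline(baseline, path)
        again = read_baseline(path)
        pd.testing.assert_frame_equal(baseline.means, again.means)


class TestImputation:
    def test_complete_panel_passes_through_unchanged(self):
        panel = _panel(np.arange(60.0))
        res = impute_missing(panel, n_imputations=3, seed=0)
        for comp in res.completed:
            np.testing.assert_array_equal(comp.values, panel.values)

    def test_observed_cells_never_altered(self, study_panel):
        panel, _ = study_panel
        res = impute_missing(panel, n_imputations=3, seed=1)
        keep = ~panel.missing_mask
        for comp in res.completed:
            np.testing.assert_array_equal(comp.values[keep], panel.values[keep])
        assert res.consensus.is_complete

    def test_deterministic_under_fixed_seed(self, study_panel):
        panel, _ = study_panel
        a = impute_missing(panel, n_imputations=2, seed=5)
        b = impute_missing(panel, n_imputations=2, seed=5)
        np.testing.assert_array_equal(a.consensus.values, b.consensus.values)

    def test_interior_gap_in_linear_trend_lands_between_neighbors(self):
        t = np.arange(80.0)
        values = np.column_stack([2.0 * t + 5.0, -t])
        values[40, 0] = np.nan
        panel = _panel(values)
        res = impute_missing(panel, n_imputations=5, seed=2)
        est = res.consensus.values[40, 0]
        lo, hi = values[39, 0], values[41, 0]  # 83, 87
        margin = 0.5 * (hi - lo)  # posterior-noise allowance
        assert lo - margin < est < hi + margin

    def test_beats_month_mean_fill_on_held_out_cells(self):
        """Consensus RMSE < month-mean-fill RMSE, pooled over seeded replicates."""
        mi_sq, month_sq = [], []
        for s in (21, 31, 41):
            panel, _ = make_study_like_panel(
                StudyScenarioConfig(seed=s, missing_rate=0.0)
            )
            truth = panel.values.copy()
            masked = inject_missing(panel, 0.05, seed=s + 1)
            res = impute_missing(masked, n_imputations=5, seed=s + 2)
            month = masked.dates.month.to_numpy()
            hold = masked.missing_mask

            def sq_errors(filled):
                out = []
                for j in range(truth.shape[1]):
                    sd = truth[:, j].std()
                    out.append(((filled[:, j] - truth[:, j])[hold[:, j]] / sd) ** 2)
                return np.concatenate(out)

            month_fill = truth.copy()
            for j in range(truth.shape[1]):
                for mo in np.unique(month):
                    rows = (month == mo) & ~hold[:, j]
                    cells = (month == mo) & hold[:, j]
                    month_fill[cells, j] = truth[rows, j].mean()
            mi_sq.append(sq_errors(res.consensus.values))
            month_sq.append(sq_errors(month_fill))
        mi_rmse = np.sqrt(np.concatenate(mi_sq).mean())
        month_rmse = np.sqrt(np.concatenate(month_sq).mean())
        assert mi_rmse < month_rmse

    def test_fully_missing_variable_rejected(self):
        values = np.column_stack([np.arange(40.0), np.full(40, np.nan)])
        with pytest.raises(PanelError, match="fully missing"):
            impute_missing(_panel(values), seed=0)


class TestSeasonalAdjust:
    def test_exact_subtraction(self):
        panel = _panel(np.full(31, 10.0), start="2020-01-01")
        baseline = MonthlyBaseline.from_dict({"v0": 4.0})
        out = seasonal_adjust(panel, baseline)
        assert np.all(out.values == 6.0)

    def test_values_equal_to_baseline_give_zero(self):
        panel = _panel(np.full(60, 3.5))
        out = seasonal_adjust(panel, MonthlyBaseline.from_dict({"v0": 3.5}))
        assert np.all(out.values == 0.0)

    def test_zero_baseline_preserves_series(self):
        panel, baseline = make_study_like_panel(
            StudyScenarioConfig(seed=7, missing_rate=0.0)
        )
        out = seasonal_adjust(panel, baseline)
        np.testing.assert_array_equal(out.values[:, 0], panel.values[:, 0])
        assert out.values[:, 0].min() == 0.0  # epidemic minimum survives adjustment

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(10, 2, size=90)
        panel = _panel(raw)
        b = MonthlyBaseline.from_dict({"v0": 4.0})
        b3 = MonthlyBaseline.from_dict({"v0": 12.0})
        one = seasonal_adjust(panel, b).values
        three = seasonal_adjust(_panel(3.0 * raw), b3).values
        np.testing.assert_allclose(three, 3.0 * one, rtol=1e-12)

    def test_unknown_variable_in_baseline_rejected(self):
        panel = _panel(np.arange(40.0))
        baseline = MonthlyBaseline.from_dict({"other": 1.0})
        with pytest.raises(PanelError, match="no baseline"):
            seasonal_adjust(panel, baseline)

    def test_incomplete_panel_rejected(self):
        values = np.arange(40.0)
        values[3] = np.nan
        with pytest.raises(PanelError, match="complete"):
            seasonal_adjust(_panel(values), MonthlyBaseline.from_dict({"v0": 0.0}))


class TestDescribe:
    def test_small_series_stats(self):
        stats = describe(_panel([1.0, 2.0, 3.0])).table
        row = stats.loc["v0"]
        assert row["N"] == 3 and row["Mean"] == 2.0
        assert row["Min"] == 1.0 and row["Max"] == 3.0
        assert row["Std. Dev."] == pytest.approx(1.0)

    def test_constant_series_has_zero_sd(self):
        stats = describe(_panel(np.full(10, 7.0))).table
        assert stats.loc["v0", "Std. Dev."] == 0.0

    def test_adjustment_shifts_mean_by_month_weighted_baseline(self):
        panel, _ = make_study_like_panel(StudyScenarioConfig(seed=4, missing_rate=0.0))
        baseline = MonthlyBaseline.from_dict(
            {"new": 0.0, "pas": np.arange(1.0, 13.0), "pek": 5.0}
        )
        before = describe(panel).table["Mean"]
        after = describe(seasonal_adjust(panel, baseline)).table["Mean"]
        months = panel.dates.month.to_numpy()
        for var in ("new", "pas", "pek"):
            per_month = np.array([baseline.lookup(var, mo) for mo in months])
            assert after[var] == pytest.approx(before[var] - per_month.mean(), rel=1e-12)

    def test_empty_panel_rejected(self):
        with pytest.raises((PanelError, ValueError)):
            describe(
                DailySeriesPanel(
                    pd.date_range("2020-01-01", periods=1),
                    np.empty((1, 0)),
                    np.empty((1, 0), dtype=bool),
                    (),
                )
            )
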