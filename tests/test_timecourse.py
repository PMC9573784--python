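"""Worked examples and properties of the time-course analysis."""

import numpy as np
import pandas as pd
import pytest

from carpelkit.synthetic import (TemperatureSeries, TrajectoryParams,
                                 generate_temperature_series,
                                 generate_trajectory_set)
from carpelkit.timecourse import (LoessSmoother, PhaseReport, SmoothedCurve,
                                  classify_phases, cumulative_degree_days,
                                  iqr_filter, loess_smooth, rank_cultivars,
                                  thermal_time_at)


def _df(values, cultivar="A", timepoint=0.0):
    return pd.DataFrame({"cultivar": cultivar, "timepoint_days": timepoint,
                         "stigma_area_mm2": values})


class TestIqrFilter:
    def test_worked_example(self):
        # [1, 2, 3, 4, 100]: Q1=2, Q3=4, IQR=2 -> fence [-1, 7] drops 100
        df = _df([1.0, 2.0, 3.0, 4.0, 100.0])
        kept, removed = iqr_filter(df, "stigma_area_mm2")
        assert removed["stigma_area_mm2"].tolist() == [100.0]
        assert kept["stigma_area_mm2"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_all_equal_keeps_everything(self):
        df = _df([5.0] * 6)
        kept, removed = iqr_filter(df, "stigma_area_mm2")
        assert len(removed) == 0 and len(kept) == 6

    def test_small_groups_pass_through(self):
        df = _df([1.0, 2.0, 1000.0])
        kept, removed = iqr_filter(df, "stigma_area_mm2")
        assert len(removed) == 0 and len(kept) == 3

    def test_groups_filtered_independently(self):
        df = pd.concat([_df([1, 2, 3, 4, 100.0], timepoint=0.0),
                        _df([90, 95, 100, 105, 110.0], timepoint=3.0)],
                       ignore_index=True)
        kept, removed = iqr_filter(df, "stigma_area_mm2")
        assert removed["timepoint_days"].tolist() == [0.0]
        assert (kept.query("timepoint_days == 3.0")["stigma_area_mm2"]
                .tolist() == [90, 95, 100, 105, 110])

    def test_idempotent_on_typical_data(self):
        rng = np.random.default_rng(0)
        df = _df(np.exp(rng.normal(0, 0.3, 30)))
        once, _ = iqr_filter(df, "stigma_area_mm2")
        twice, removed2 = iqr_filter(once, "stigma_area_mm2")
        # second pass can remove at most a point or two of a clean sample,
        # and never re-adds anything
        assert len(twice) <= len(once)
        assert set(twice.index) <= set(once.index)

    def test_row_order_preserved(self):
        df = _df([3.0, 1.0, 100.0, 4.0, 2.0])
        kept, _ = iqr_filter(df, "stigma_area_mm2")
        assert kept["stigma_area_mm2"].tolist() == [3.0, 1.0, 4.0, 2.0]


class TestLoess:
    def test_reproduces_polynomials_exactly(self):
        # local-quadratic loess is exact on degree <= 2 polynomials
        t = np.linspace(0, 10, 25)
        for f in (lambda x: 2 * x + 1, lambda x: 0.5 * x ** 2 - x + 3):
            curve = loess_smooth(t, f(t), span=0.9)
            assert np.allclose(curve.mean, f(curve.grid), atol=1e-8)
            # zero residuals -> zero-width CI
            assert np.allclose(curve.ci_high - curve.ci_low, 0.0, atol=1e-6)

    def test_ci_covers_mean_and_widens_with_noise(self):
        rng = np.random.default_rng(2)
        t = np.repeat(np.arange(0, 10.0), 4)
        y_clean = 5 + np.sin(t / 3)
        small = loess_smooth(t, y_clean + rng.normal(0, 0.01, t.size))
        big = loess_smooth(t, y_clean + rng.normal(0, 0.3, t.size))
        assert np.all(small.ci_low <= small.mean)
        assert np.all(small.mean <= small.ci_high)
        assert (big.ci_high - big.ci_low).mean() \
            > (small.ci_high - small.ci_low).mean()

    def test_estimator_api_and_validation(self):
        t = np.array([0.0, 1, 2, 3, 4, 5])
        sm = LoessSmoother(span=0.9).fit(t, t * 2)
        assert sm.get_params()["span"] == 0.9
        assert np.allclose(sm.predict([2.5]), [5.0])
        with pytest.raises(ValueError, match="distinct"):
            LoessSmoother().fit([0, 0, 0, 1, 1, 1], [1, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="span"):
            LoessSmoother(span=1.5).fit(t, t)

    def test_peak_recovery_under_noise(self):
        # the smoothed argmax should land within one sampling interval of the
        # true peak in >= 90% of seeded replicates (CV = 0.1, n = 5/timepoint)
        params = TrajectoryParams()
        hits = 0
        for rep in range(100):
            ts = generate_trajectory_set(params, seed=1000 + rep)
            curve = loess_smooth(ts.records["timepoint_days"],
                                 ts.records["stigma_area_mm2"], span=0.9)
            t_hat = curve.grid[int(np.argmax(curve.mean))]
            # widest neighbouring sampling interval around t_peak = 6: [3, 7]
            if 3.0 <= t_hat <= 7.0 + 1e-9:
                hits += 1
        assert hits >= 90


class TestDegreeDays:
    def test_worked_examples(self):
        ts = TemperatureSeries(
            dates=pd.date_range("2020-05-01", periods=3, freq="D"),
            daily_mean=np.array([10.0, 12.0, 8.0]))
        assert cumulative_degree_days(ts, 0, 2) == 30.0
        assert cumulative_degree_days(ts, 1, 1) == 12.0
        ts2 = TemperatureSeries(
            dates=pd.date_range("2020-05-01", periods=2, freq="D"),
            daily_mean=np.array([-2.0, 5.0]))
        assert cumulative_degree_days(ts2, 0, 1) == 5.0   # clamped at base 0

    def test_fractional_interpolation(self):
        ts = TemperatureSeries(
            dates=pd.date_range("2020-05-01", periods=3, freq="D"),
            daily_mean=np.array([10.0, 12.0, 8.0]))
        assert thermal_time_at(ts, 0.0) == 0.0
        assert thermal_time_at(ts, 1.0) == 10.0
        assert thermal_time_at(ts, 1.5) == 16.0
        assert thermal_time_at(ts, 3.0) == 30.0

    def test_additivity_and_consistency(self):
        ts = generate_temperature_series(30, seed=5)
        a = cumulative_degree_days(ts, 0, 9)
        b = cumulative_degree_days(ts, 10, 19)
        assert a + b == pytest.approx(cumulative_degree_days(ts, 0, 19))
        # inclusive [i, j] window equals thermal time over [i, j+1)
        assert cumulative_degree_days(ts, 3, 7) == pytest.approx(
            thermal_time_at(ts, 8.0) - thermal_time_at(ts, 3.0))

    def test_bounds_checked(self):
        ts = generate_temperature_series(5, seed=0)
        with pytest.raises(IndexError):
            cumulative_degree_days(ts, 0, 5)
        with pytest.raises(IndexError):
            cumulative_degree_days(ts, 3, 2)
        with pytest.raises(IndexError):
            thermal_time_at(ts, 5.5)
        with pytest.raises(ValueError):
            thermal_time_at(ts, -1.0)


def _curve(grid, vals):
    grid = np.asarray(grid, dtype=float)
    vals = np.asarray(vals, dtype=float)
    return SmoothedCurve(grid=grid, mean=vals, ci_low=vals, ci_high=vals,
                         span=0.9)


class TestClassifyPhases:
    def test_triangular_worked_example(self):
        # linear rise 0->10 over [0, 10], fall 10->0 over [10, 20]:
        # 85% rise at 8.5; 15% drop at 11.5; 40% drop at 14.0
        grid = np.arange(0.0, 20.0 + 1e-9, 0.1)
        vals = np.where(grid <= 10, grid, 20 - grid)
        rep = classify_phases(_curve(grid, vals), cultivar="T")
        assert rep.growth_end == pytest.approx(8.5, abs=1e-6)
        assert rep.peak_onset == pytest.approx(10.0, abs=1e-6)
        assert rep.peak_end == pytest.approx(11.5, abs=1e-6)
        assert rep.deterioration_marker_40pct == pytest.approx(14.0, abs=1e-6)
        assert rep.durations_days == {"growth": pytest.approx(8.5),
                                      "peak": pytest.approx(3.0),
                                      "deterioration": pytest.approx(8.5)}
        assert rep.censored == set()

    def test_interpolation_between_grid_points(self):
        # coarse grid: the 15% crossing falls between grid nodes
        grid = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        vals = np.array([0.0, 5.0, 10.0, 5.0, 0.0])
        rep = classify_phases(_curve(grid, vals))
        assert rep.peak_end == pytest.approx(10 + 1.5 / 5 * 5, abs=1e-9)

    def test_monotone_rise_is_censored(self):
        grid = np.arange(0.0, 10.0 + 1e-9, 0.1)
        rep = classify_phases(_curve(grid, grid))
        assert rep.peak_end is None
        assert rep.deterioration_marker_40pct is None
        assert rep.censored == {"peak_end", "deterioration_marker_40pct"}
        assert rep.durations_days["peak"] is None

    def test_constant_curve_degenerate(self):
        grid = np.arange(0.0, 10.0 + 1e-9, 0.1)
        rep = classify_phases(_curve(grid, np.full_like(grid, 3.0)))
        assert rep.growth_end == 0.0
        assert rep.peak_onset == 0.0
        assert rep.peak_end is None   # never drops below 85%

    def test_degree_day_durations(self):
        ts = TemperatureSeries(
            dates=pd.date_range("2020-05-01", periods=21, freq="D"),
            daily_mean=np.full(21, 10.0))
        grid = np.arange(0.0, 20.0 + 1e-9, 0.1)
        vals = np.where(grid <= 10, grid, 20 - grid)
        rep = classify_phases(_curve(grid, vals), temperature=ts)
        # constant 10 degC -> degree days = 10 x days
        assert rep.durations_degree_days["growth"] == pytest.approx(85.0)
        assert rep.durations_degree_days["peak"] == pytest.approx(30.0)
        assert rep.durations_degree_days["deterioration"] == pytest.approx(85.0)

    def test_curve_must_cover_window(self):
        grid = np.arange(2.0, 10.0, 0.1)
        with pytest.raises(ValueError, match="cover"):
            classify_phases(_curve(grid, grid))

    def test_noiseless_pipeline_recovers_true_boundaries(self):
        # zero-noise records -> loess -> classification matches the analytic
        # boundaries to within one grid step
        params = TrajectoryParams(noise_cv=0.0,
                                  timepoints=(0, 2, 4, 6, 8, 10, 13, 16, 18))
        ts = generate_trajectory_set(params, seed=0)
        grid = np.arange(0.0, 18.0 + 1e-9, 0.1)
        curve = loess_smooth(ts.records["timepoint_days"],
                             ts.records["stigma_area_mm2"], span=0.5,
                             grid=grid)
        rep = classify_phases(curve, cultivar=params.cultivar_id)
        tb = ts.true_boundaries
        assert rep.peak_end == pytest.approx(tb["peak_end"], abs=0.5)
        assert rep.deterioration_marker_40pct == pytest.approx(
            tb["deterioration_marker_40pct"], abs=0.5)
        assert rep.growth_end == pytest.approx(tb["growth_end"], abs=0.5)


class TestRanking:
    def _report(self, cultivar, peak_end, marker=None, season="s"):
        return PhaseReport(cultivar=cultivar, growth_end=1.0, peak_onset=2.0,
                           peak_end=peak_end,
                           deterioration_marker_40pct=marker,
                           last_sampling=20.0, season=season)

    def test_three_cultivars_get_tempo_labels(self):
        ranking = rank_cultivars([self._report("B", 10.0),
                                  self._report("A", 14.0),
                                  self._report("C", 8.0)])
        assert ranking["cultivar"].tolist() == ["A", "B", "C"]
        assert ranking["tempo"].tolist() == ["slow", "moderate", "fast"]
        assert ranking["rank"].tolist() == [1, 2, 3]

    def test_censored_ranks_slowest(self):
        ranking = rank_cultivars([self._report("A", 14.0),
                                  self._report("B", None)])
        assert ranking["cultivar"].tolist() == ["B", "A"]
        assert ranking["tempo"].tolist() == ["rank_1", "rank_2"]

    def test_ties_break_on_marker_then_label(self):
        ranking = rank_cultivars([self._report("A", 10.0, marker=12.0),
                                  self._report("B", 10.0, marker=15.0),
                                  self._report("C", 10.0, marker=15.0)])
        assert ranking["cultivar"].tolist() == ["B", "C", "A"]

    def test_mixed_seasons_rejected(self):
        with pytest.raises(ValueError, match="season"):
            rank_cultivars([self._report("A", 10.0, season="2019"),
                            self._report("B", 11.0, season="2020")])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            rank_cultivars([self._report("A", 10.0)])
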