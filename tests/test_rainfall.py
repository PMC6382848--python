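"""Rainfall metric definitions: climatology, seasonality index, wet-season
detection, intensity/frequency statistics and the water-balance identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from tgbcover import (
    SI_MAX,
    DailyRainfallSeries,
    MonthlyClimatology,
    calibrate_pthr,
    compute_metrics,
    mean_annual_rainfall,
    monthly_climatology,
    season_length_from_si,
    seasonality_index,
    wet_day_stats,
    wet_season,
)
from tgbcover._calendar import MONTH_LENGTHS, MONTH_OF_DAY, day_mask
from tgbcover.rainfall import SeasonalityUndefinedError

from conftest import series_from_monthly


class TestClimatologyAndMar:
    def test_all_zero_series_gives_zero_climatology(self):
        clim = monthly_climatology(DailyRainfallSeries(np.zeros((2, 365))))
        assert np.all(clim.mean_monthly == 0)
        assert clim.annual_mean == 0

    def test_one_mm_per_day(self, uniform_series):
        clim = monthly_climatology(uniform_series)
        assert clim.mean_monthly[0] == pytest.approx(31.0)
        assert clim.annual_mean == pytest.approx(365.0)
        assert mean_annual_rainfall(uniform_series) == pytest.approx(365.0)

    def test_climatology_averages_over_years(self):
        depths = np.vstack([np.zeros((1, 365)), np.ones((1, 365))])
        clim = monthly_climatology(DailyRainfallSeries(depths))
        assert clim.mean_monthly[0] == pytest.approx(15.5)

    def test_mar_matches_climatology_annual_mean(self):
        rng = np.random.default_rng(0)
        series = DailyRainfallSeries(rng.exponential(2.0, size=(3, 365)))
        clim = monthly_climatology(series)
        assert mean_annual_rainfall(series) == pytest.approx(
            clim.annual_mean, rel=1e-9
        )

    def test_constant_two_mm(self):
        series = DailyRainfallSeries(np.full((4, 365), 2.0))
        assert mean_annual_rainfall(series) == pytest.approx(730.0)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            DailyRainfallSeries(np.zeros((1, 366)))
        with pytest.raises(ValueError):
            DailyRainfallSeries(-np.ones((1, 365)))


class TestSeasonalityIndex:
    def test_uniform_rain_gives_zero(self):
        clim = MonthlyClimatology(np.full(12, 100.0))
        assert seasonality_index(clim) == pytest.approx(0.0)

    def test_single_month_gives_max(self):
        monthly = np.zeros(12)
        monthly[0] = 1200.0
        assert seasonality_index(MonthlyClimatology(monthly)) == pytest.approx(
            22.0 / 12.0
        )

    def test_two_equal_months(self):
        monthly = np.zeros(12)
        monthly[[0, 6]] = 600.0
        assert seasonality_index(MonthlyClimatology(monthly)) == pytest.approx(
            20.0 / 12.0
        )

    def test_zero_rain_raises(self):
        with pytest.raises(SeasonalityUndefinedError):
            seasonality_index(MonthlyClimatology(np.zeros(12)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
            min_size=12,
            max_size=12,
        ).filter(lambda v: sum(v) > 1e-6)
    )
    def test_bounds(self, monthly):
        si = seasonality_index(MonthlyClimatology(np.array(monthly)))
        assert 0.0 <= si <= SI_MAX + 1e-12


class TestWetSeason:
    def test_uniform_rain_all_months_wet(self, uniform_series):
        months, l_w = wet_season(monthly_climatology(uniform_series), 0.5)
        assert months == frozenset(range(1, 13))
        assert l_w == 365

    def test_all_rain_in_july(self):
        monthly = np.zeros(12)
        monthly[6] = 500.0
        months, l_w = wet_season(MonthlyClimatology(monthly), 0.5)
        assert months == frozenset({7})
        assert l_w == 31

    def test_zero_climatology_empty_season(self):
        months, l_w = wet_season(MonthlyClimatology(np.zeros(12)), 0.5)
        assert months == frozenset()
        assert l_w == 0

    def test_tie_counts_as_dry(self):
        # month exactly at the threshold is not wet (strict inequality)
        monthly = np.full(12, 100.0)
        monthly[0] = 0.0
        clim = MonthlyClimatology(monthly)
        thr_month = 0.5 * clim.annual_mean / 12.0
        monthly[0] = thr_month
        months, _ = wet_season(MonthlyClimatology(monthly), 0.5)
        assert 1 not in months

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e3, allow_nan=False),
            min_size=12,
            max_size=12,
        ).filter(lambda v: sum(v) > 1e-6),
        st.floats(min_value=0.05, max_value=0.45),
        st.floats(min_value=0.5, max_value=0.95),
    )
    def test_length_non_increasing_in_threshold(self, monthly, p_low, p_high):
        clim = MonthlyClimatology(np.array(monthly))
        _, l_low = wet_season(clim, p_low)
        _, l_high = wet_season(clim, p_high)
        assert l_high <= l_low


class TestSeasonLengthFromSi:
    def test_endpoints(self):
        assert season_length_from_si(0.0) == pytest.approx(365.0)
        assert season_length_from_si(1.83) == pytest.approx(365.0 / 12.0)

    def test_midpoint(self):
        assert season_length_from_si(0.915) == pytest.approx(365.0 / 12.0 * 6.5)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.0, SI_MAX, 50)
        values = [season_length_from_si(s) for s in grid]
        assert np.all(np.diff(values) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            season_length_from_si(-0.2)
        with pytest.raises(ValueError):
            season_length_from_si(2.0)


class TestWetDayStats:
    WET = frozenset({1, 2, 3, 4})

    def test_constant_wet_season(self):
        depths = np.zeros((2, 365))
        depths[:, day_mask(self.WET)] = 5.0
        stats = wet_day_stats(DailyRainfallSeries(depths), self.WET)
        assert stats.alpha_w == pytest.approx(5.0)
        assert stats.lambda_w == pytest.approx(1.0)
        assert stats.c == pytest.approx(0.0, abs=1e-9)

    def test_sub_threshold_rain_goes_to_c(self):
        depths = np.zeros((1, 365))
        depths[:, day_mask(self.WET)] = 0.05
        stats = wet_day_stats(DailyRainfallSeries(depths), self.WET)
        assert stats.lambda_w == 0.0
        assert np.isnan(stats.alpha_w)
        assert stats.c == pytest.approx(stats.mar_w)

    def test_identity_exact_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            depths = rng.exponential(3.0, size=(3, 365)) * (
                rng.random((3, 365)) < 0.4
            )
            l_w = int(MONTH_LENGTHS[[m - 1 for m in self.WET]].sum())
            stats = wet_day_stats(DailyRainfallSeries(depths), self.WET)
            resid = stats.mar_w - (stats.alpha_w * stats.lambda_w * l_w + stats.c)
            assert abs(resid) <= 1e-9 * max(1.0, stats.mar_w)

    def test_agrees_with_naive_loop(self):
        """Oracle: day-by-day accumulation of wet-day depths and counts."""
        rng = np.random.default_rng(7)
        depths = rng.exponential(4.0, size=(2, 365)) * (rng.random((2, 365)) < 0.3)
        series = DailyRainfallSeries(depths)
        stats = wet_day_stats(series, self.WET, 0.1)

        total, count, season_total = 0.0, 0, 0.0
        for year in range(series.n_years):
            for day in range(365):
                if MONTH_OF_DAY[day] in self.WET:
                    season_total += depths[year, day]
                    if depths[year, day] > 0.1:
                        total += depths[year, day]
                        count += 1
        l_w = int(MONTH_LENGTHS[[m - 1 for m in self.WET]].sum())
        assert stats.alpha_w == pytest.approx(total / count)
        assert stats.lambda_w == pytest.approx(count / series.n_years / l_w)
        assert stats.mar_w == pytest.approx(season_total / series.n_years)

    def test_empty_wet_months_rejected(self):
        with pytest.raises(ValueError):
            wet_day_stats(DailyRainfallSeries(np.ones((1, 365))), frozenset())


def _calibration_cell(heavy, shoulder, sub):
    """A cell whose threshold-rule wet-season length at p=0.5 equals its
    SI-mapped length exactly: ``heavy`` months at 100 mm, a ``shoulder``
    month tuned so SI hits the value that maps to L_w, and a ``sub`` month
    pinned at 35% of the mean monthly rain (wet at p=0.2, dry at p=0.5)."""
    wet = list(heavy) + [shoulder]
    l_w = int(MONTH_LENGTHS[[m - 1 for m in wet]].sum())
    si_star = 1.83 * (1.0 - (12.0 * l_w / 365.0 - 1.0) / 11.0)

    def build(v, u):
        monthly = np.zeros(12)
        monthly[[m - 1 for m in heavy]] = 100.0
        monthly[shoulder - 1] = v
        monthly[sub - 1] = u
        return monthly

    u = 0.0
    for _ in range(60):
        def gap(v):
            monthly = build(v, u)
            total = monthly.sum()
            return np.abs(monthly - total / 12.0).sum() / total - si_star

        v = brentq(gap, 1.0, 100.0, xtol=1e-13)
        u_new = 0.35 * build(v, u).sum() / 12.0
        if abs(u_new - u) < 1e-12:
            break
        u = u_new
    return series_from_monthly(build(v, u))


class TestCalibratePthr:
    def test_constructed_cells_choose_half(self):
        cells = [
            _calibration_cell([1, 3], 2, 4),
            _calibration_cell([1, 2, 3, 4], 6, 5),
            _calibration_cell([1, 2, 3, 4, 5, 6], 7, 12),
        ]
        cal = calibrate_pthr(cells, [0.2, 0.5, 0.7])
        assert cal.chosen == 0.5
        curve = cal.as_dict()
        assert curve[0.5] == pytest.approx(1.0, abs=1e-9)
        assert curve[0.2] < 1.0 - 1e-6
        assert curve[0.7] < 1.0 - 1e-6

    def test_single_candidate_returned_unchanged(self):
        cells = [series_from_monthly(np.arange(12) * 10.0)]
        assert calibrate_pthr(cells, [0.4]).chosen == 0.4

    def test_aseasonal_cells_degenerate(self):
        cells = [series_from_monthly(np.full(12, 50.0)) for _ in range(4)]
        with pytest.raises(ValueError):
            calibrate_pthr(cells, [0.3, 0.5])

    def test_realistic_grid_high_correlation_at_half(self):
        from tgbcover import RainGenParams, simulate_daily_rainfall

        cells = []
        for i, n_months in enumerate([2, 3, 4, 5, 6, 7, 8, 9, 10] * 4):
            params = RainGenParams(
                n_years=8,
                wet_months=frozenset(((i + j) % 12) + 1 for j in range(n_months)),
                event_prob=0.45,
                mean_depth=9.0,
                seed=100 + i,
            )
            cells.append(simulate_daily_rainfall(params))
        cal = calibrate_pthr(cells, [0.3, 0.5, 0.7])
        assert cal.as_dict()[0.5] >= 0.9


class TestComputeMetrics:
    def test_combined_metrics_consistency(self):
        from tgbcover import RainGenParams, simulate_daily_rainfall

        params = RainGenParams(
            n_years=10,
            wet_months=frozenset({12, 1, 2, 3, 4}),
            event_prob=0.4,
            mean_depth=10.0,
            seed=1,
        )
        m = compute_metrics(simulate_daily_rainfall(params))
        assert m.mar_w <= m.mar + 1e-9
        assert 0.0 <= m.lambda_w <= 1.0
        assert m.alpha_w > 0.1
        resid = m.mar_w - (m.alpha_w * m.lambda_w * m.l_w + m.c)
        assert abs(resid) <= 1e-6 * max(1.0, m.mar_w)
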