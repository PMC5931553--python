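"""Climate metrics: regional SIC, phenology, station stacking, trends."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from arclake.climate import (
    StationSeries,
    annual_series,
    ice_phenology,
    linear_trend,
    melting_season_length,
    period_phenology,
    regional_mean_sic,
    site_temperature,
    stack_stations,
)


def daily(values, start="2000-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def year_series(year, value):
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return pd.Series(np.full(idx.size, float(value)), index=idx)


class TestRegionalMeanSic:
    def _grid(self, data):
        t = pd.date_range("2000-01-01", periods=data.shape[0], freq="D")
        return xr.DataArray(data, dims=("time", "y", "x"), coords={"time": t})

    def test_uniform_field(self):
        s = regional_mean_sic(self._grid(np.full((4, 3, 3), 80.0)))
        assert np.allclose(s.values, 80.0)

    def test_half_and_half(self):
        data = np.zeros((2, 2, 2))
        data[:, 0, :] = 100.0
        assert np.allclose(regional_mean_sic(self._grid(data)).values, 50.0)

    def test_spatially_uniform_doy_function_passes_through(self):
        f = 50.0 + 30.0 * np.sin(np.arange(10))
        data = np.tile(f[:, None, None], (1, 4, 4))
        np.testing.assert_allclose(regional_mean_sic(self._grid(data)).values, f)

    def test_land_cells_ignored_and_sparse_days_masked(self):
        data = np.full((4, 2, 2), 60.0)
        data[:, 0, 0] = np.nan            # land cell
        data[2, :, :] = np.nan
        data[2, 1, 1] = 60.0              # only 1/3 ocean cells report
        s = regional_mean_sic(self._grid(data), min_valid_fraction=0.5)
        assert np.isnan(s.iloc[2]) and s.iloc[0] == 60.0

    def test_long_format_with_cell_selection(self):
        rows = []
        for d in pd.date_range("2000-01-01", periods=3, freq="D"):
            rows += [
                {"date": d, "cell_id": "a", "sic_percent": 100.0},
                {"date": d, "cell_id": "b", "sic_percent": 0.0},
                {"date": d, "cell_id": "c", "sic_percent": 40.0},
            ]
        df = pd.DataFrame(rows)
        assert np.allclose(regional_mean_sic(df, region={"cells": ["a", "b"]}).values, 50.0)

    def test_empty_region_raises(self):
        df = pd.DataFrame({"date": ["2000-01-01"], "cell_id": ["a"], "sic_percent": [10.0]})
        with pytest.raises(ValueError):
            regional_mean_sic(df, region={"cells": ["zzz"]})


class TestIcePhenology:
    def test_permanent_ice(self):
        ph = ice_phenology(year_series(2001, 100.0), 2001)
        assert ph.ice_free_days == 0 and ph.high_ice_days == 365
        assert np.isnan(ph.melt_onset_doy)

    def test_open_water_all_year(self):
        ph = ice_phenology(year_series(2001, 0.0), 2001)
        assert ph.ice_free_days == 365 and ph.melt_onset_doy == 1.0
        ph_leap = ice_phenology(year_series(2004, 0.0), 2004)
        assert ph_leap.ice_free_days == 366

    def test_counts_match_analytic_window(self, clean_climate):
        _, sic, _, truth = clean_climate
        for year in (1970, 1990, 2005, 2014):
            ph = ice_phenology(sic, year)
            assert abs(ph.ice_free_days - truth.ice_free_days(year)) <= 1.0 + 1e-9
            start, _ = truth.below_threshold_window(year)
            assert abs(ph.melt_onset_doy - start) <= 1.0 + 1e-9

    def test_day_accounting_is_exact(self, noisy_climate):
        _, sic, _, _ = noisy_climate
        for year in (1965, 1988, 2010):
            sel = sic.loc[f"{year}-01-01":f"{year}-12-31"]
            days = pd.Timestamp(year, 12, 31).dayofyear
            ph = ice_phenology(sic, year)
            at_or_above = int((sel.dropna() >= 55.0).sum())
            missing = days - sel.notna().sum()
            assert ph.ice_free_days + at_or_above + missing == days

    def test_order_invariance(self, noisy_climate):
        _, sic, _, _ = noisy_climate
        shuffled = sic.sample(frac=1.0, random_state=0)
        a = ice_phenology(sic, 2000)
        b = ice_phenology(shuffled, 2000)
        assert a == b

    def test_low_coverage_flagged(self):
        s = year_series(2001, 20.0).iloc[:100]
        assert ice_phenology(s, 2001).low_coverage


class TestPeriodPhenology:
    def test_identical_years_mean_equals_each(self, clean_climate):
        _, sic, _, _ = clean_climate
        p = period_phenology(sic, [1991, 1991])
        assert p.mean["ice_free_days"] == p.per_year["ice_free_days"].iloc[0]

    def test_two_year_average(self):
        s = pd.concat([year_series(2001, 0.0), year_series(2002, 100.0)])
        # 2001 all open (365 free), 2002 all ice (0 free) -> mean 182.5
        p = period_phenology(s, [2001, 2002])
        assert p.mean["ice_free_days"] == pytest.approx(182.5)

    def test_period_difference_matches_imposed_shift(self):
        """30-yr scenario with +-10 d/decade: decadal difference of period
        means equals the imposed widening within 2 days."""
        from arclake.synthetic import ClimateScenario, ClimateTruth, gen_daily_climate

        sc = ClimateScenario(start_year=1985, end_year=2014,
                             melt_trend_days_per_decade=10.0,
                             freeze_trend_days_per_decade=10.0, seed=42)
        sic, _, truth = gen_daily_climate(sc)
        early = period_phenology(sic, range(1985, 1995)).mean["ice_free_days"]
        late = period_phenology(sic, range(2005, 2015)).mean["ice_free_days"]
        an_early = np.mean([truth.ice_free_days(y) for y in range(1985, 1995)])
        an_late = np.mean([truth.ice_free_days(y) for y in range(2005, 2015)])
        got = (late - early) / 2.0      # per decade between period centres
        expect = (an_late - an_early) / 2.0
        assert got == pytest.approx(expect, abs=2.0)

    def test_no_qualifying_years_raises(self):
        s = year_series(2001, 50.0).iloc[:50]
        with pytest.raises(ValueError):
            period_phenology(s, [2001])


class TestStations:
    def test_identical_stations_blend_to_themselves(self):
        s = StationSeries("a", year_series(2001, -5.0), year_series(2001, -2.0))
        t = StationSeries("b", year_series(2001, -5.0), year_series(2001, -2.0))
        blended = stack_stations([s, t])
        assert blended.tmean.equals(s.tmean)

    def test_offset_pair_averages(self):
        s = StationSeries("a", year_series(2001, 1.0), year_series(2001, 4.0))
        t = StationSeries("b", year_series(2001, 3.0), year_series(2001, 6.0))
        blended = stack_stations([s, t])
        assert np.allclose(blended.tmean.values, 2.0)
        assert np.allclose(blended.tmax.values, 5.0)

    def test_min_stations_masks_days(self):
        a = StationSeries("a", year_series(2001, 1.0), year_series(2001, 2.0))
        short = year_series(2001, 3.0).iloc[:100]
        b = StationSeries("b", short, short + 1)
        blended = stack_stations([a, b], min_stations=2)
        assert blended.tmean.notna().sum() == 100

    def test_site_offset_shifts_every_day(self):
        s = StationSeries("a", year_series(2001, 3.0), year_series(2001, 5.0))
        site = site_temperature(s, offset=-1.6)
        assert np.allclose(site.tmean.values, 1.4)
        assert annual_series(site.tmean).iloc[0] == pytest.approx(
            annual_series(s.tmean).iloc[0] - 1.6
        )
        assert site.metadata["offset_c"] == -1.6

    def test_max_below_mean_rejected(self):
        with pytest.raises(ValueError, match="below"):
            StationSeries("bad", year_series(2001, 5.0), year_series(2001, 4.0))


class TestMeltingSeason:
    def test_always_frozen_and_always_melting(self):
        frozen = StationSeries("f", year_series(2001, -5.0), year_series(2001, -5.0))
        warm = StationSeries("w", year_series(2004, 5.0), year_series(2004, 5.0))
        assert melting_season_length(frozen, 2001)[0] == 0
        assert melting_season_length(warm, 2004)[0] == 366

    def test_sinusoidal_window_matches_analytic(self, clean_climate):
        sc, _, stations, truth = clean_climate
        for year in (1965, 1990, 2010):
            days, cov = melting_season_length(stations[0], year)
            expect = truth.melting_window_days(year, offset=sc.station_offsets[0])
            assert cov == pytest.approx(1.0)
            assert abs(days - expect) <= 1.0 + 1e-9


class TestLinearTrend:
    def test_exact_line(self):
        years = np.arange(1960, 2016)
        tr = linear_trend(years, 2.0 * years + 3.0)
        assert tr.slope_per_decade == pytest.approx(20.0)
        assert tr.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(1)
        years = np.arange(1970, 2010, dtype=float)
        vals = 0.03 * years + rng.standard_normal(years.size)
        tr = linear_trend(years, vals)
        x, y = years - years.mean(), vals - vals.mean()
        slope = (x * y).sum() / (x * x).sum()
        assert tr.slope_per_decade == pytest.approx(10.0 * slope, abs=1e-10)

    def test_too_few_years_raises(self):
        with pytest.raises(ValueError):
            linear_trend(np.arange(5), np.arange(5.0))

    def test_constant_year_raises(self):
        with pytest.raises(ValueError):
            linear_trend(np.full(12, 2000.0), np.arange(12.0))

    def test_year_indexed_series_accepted(self):
        s = pd.Series(np.arange(12.0), index=np.arange(2000, 2012))
        assert linear_trend(s).slope_per_decade == pytest.approx(10.0)
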