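"""Sea-ice phenology, stacked-station temperature and decadal trends.

Works on daily series held as :class:`pandas.Series` with a
``DatetimeIndex`` (strictly increasing; ``NaN`` marks missing days).  Sea
ice concentration (SIC) is percent cover in [0, 100]; temperatures are °C.

The sea-ice-free period of a year is the number of days with regional-mean
SIC below a threshold (55% by default), the high-ice period the number of
days above a second threshold (75%).  Melting-season length is the number
of days whose daily maximum air temperature exceeds 0 °C.  Decadal trends
are ordinary least squares of annual values on year, reported per decade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StationSeries",
    "SeaIcePhenology",
    "PeriodPhenology",
    "TrendEstimate",
    "regional_mean_sic",
    "ice_phenology",
    "period_phenology",
    "stack_stations",
    "site_temperature",
    "melting_season_length",
    "annual_series",
    "linear_trend",
]


def _check_daily(series: pd.Series, name: str = "series") -> pd.Series:
    """Validate a daily series; returns it date-sorted (metrics are
    invariant to the order records are supplied in)."""
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError(f"{name} must be indexed by a DatetimeIndex")
    if series.index.has_duplicates:
        raise ValueError(f"{name} has duplicate dates")
    if not series.index.is_monotonic_increasing:
        return series.sort_index()
    return series


@dataclass
class StationSeries:
    """Daily mean and maximum 2-m temperature of one station (°C)."""

    name: str
    tmean: pd.Series
    tmax: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tmean = _check_daily(self.tmean, "tmean")
        self.tmax = _check_daily(self.tmax, "tmax")
        both = self.tmean.notna() & self.tmax.reindex(self.tmean.index).notna()
        if both.any():
            diff = self.tmax.reindex(self.tmean.index)[both] - self.tmean[both]
            if (diff < -1e-9).any():
                raise ValueError("daily max temperature below daily mean")


@dataclass(frozen=True)
class SeaIcePhenology:
    """Phenology of one calendar year of a daily SIC series."""

    year: int
    ice_free_days: int
    high_ice_days: int
    melt_onset_doy: float  # NaN if no sub-threshold run
    freeze_onset_doy: float
    coverage_fraction: float
    low_coverage: bool

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "year": self.year,
                "ice_free_days": self.ice_free_days,
                "high_ice_days": self.high_ice_days,
                "melt_onset_doy": self.melt_onset_doy,
                "freeze_onset_doy": self.freeze_onset_doy,
                "coverage_fraction": self.coverage_fraction,
                "low_coverage": self.low_coverage,
            }
        )


@dataclass
class PeriodPhenology:
    """Mean phenology over qualifying years plus the per-year table."""

    mean: pd.Series
    per_year: pd.DataFrame
    excluded_years: list[int]


@dataclass(frozen=True)
class TrendEstimate:
    """OLS trend of annual values, reported per decade."""

    slope_per_decade: float
    slope_se: float
    r_squared: float
    p_value: float
    n_years: int
    intercept: float = float("nan")


def regional_mean_sic(grid, region: dict | None = None, min_valid_fraction: float = 0.5) -> pd.Series:
    """Daily regional-mean SIC from a gridded field.

    ``grid`` is either an :class:`xarray.DataArray` with a ``time``
    dimension plus two spatial dimensions, or a long-format DataFrame with
    columns ``date, cell_id, sic_percent``.  ``region`` selects a box by
    coordinate ranges (xarray ``sel``-style dict of slices) or, for the long
    format, a list of cell ids under key ``"cells"``.  Land/invalid cells
    are NaN throughout; on an equal-area grid the unweighted mean over ocean
    cells is the regional mean.  Days where fewer than ``min_valid_fraction``
    of the region's ocean cells report are returned as missing.
    """
    if isinstance(grid, pd.DataFrame):
        need = {"date", "cell_id", "sic_percent"}
        if not need <= set(grid.columns):
            raise ValueError(f"long SIC table needs columns {sorted(need)}")
        df = grid
        if region and "cells" in region:
            df = df[df["cell_id"].isin(region["cells"])]
        if df.empty:
            raise ValueError("region selects no cells")
        n_cells = df["cell_id"].nunique()
        g = df.groupby("date")["sic_percent"]
        mean = g.mean()
        valid = g.count() / n_cells
        mean[valid < min_valid_fraction] = np.nan
        mean.index = pd.to_datetime(mean.index)
        return mean.sort_index()

    import xarray as xr

    da = grid
    if not isinstance(da, xr.DataArray):
        raise TypeError("grid must be an xarray.DataArray or a long-format DataFrame")
    if region:
        da = da.sel({k: v for k, v in region.items() if k in da.dims})
    spatial = [d for d in da.dims if d != "time"]
    if not spatial:
        raise ValueError("grid has no spatial dimensions")
    ocean = da.notnull().any("time")
    n_ocean = int(ocean.sum())
    if n_ocean == 0:
        raise ValueError("region contains no ocean cells")
    mean = da.where(ocean).mean(spatial, skipna=True)
    valid = da.where(ocean).notnull().sum(spatial) / n_ocean
    mean = mean.where(valid >= min_valid_fraction)
    s = mean.to_series()
    s.index = pd.to_datetime(s.index)
    return s.sort_index()


def ice_phenology(
    series: pd.Series,
    year: int,
    threshold_free: float = 55.0,
    threshold_high: float = 75.0,
    min_days: int = 300,
) -> SeaIcePhenology:
    """Sea-ice phenology of one calendar year.

    ``ice_free_days``/``high_ice_days`` count observed days below/above the
    thresholds.  Melt onset is the first day of the *longest* run of
    consecutive sub-threshold days (missing days break runs); freeze onset
    is the first day after that run.  Years with fewer than ``min_days``
    observed days are flagged ``low_coverage``.
    """
    series = _check_daily(series)
    sel = series.loc[f"{year}-01-01":f"{year}-12-31"]
    days_in_year = pd.Timestamp(year=year, month=12, day=31).dayofyear
    obs = sel.dropna()
    coverage = len(obs) / days_in_year
    ice_free = int((obs < threshold_free).sum())
    high_ice = int((obs > threshold_high).sum())

    melt = freeze = float("nan")
    if len(sel):
        full = sel.reindex(
            pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        )
        below = (full < threshold_free).to_numpy()  # NaN compares False
        best_len, best_start = 0, -1
        run_len, run_start = 0, -1
        for i, b in enumerate(below):
            if b:
                if run_len == 0:
                    run_start = i
                run_len += 1
                if run_len > best_len:
                    best_len, best_start = run_len, run_start
            else:
                run_len = 0
        if best_len > 0:
            melt = float(best_start + 1)
            freeze = float(best_start + best_len + 1)
    return SeaIcePhenology(
        year=year,
        ice_free_days=ice_free,
        high_ice_days=high_ice,
        melt_onset_doy=melt,
        freeze_onset_doy=freeze,
        coverage_fraction=coverage,
        low_coverage=len(obs) < min_days,
    )


def period_phenology(
    series: pd.Series,
    years,
    threshold_free: float = 55.0,
    threshold_high: float = 75.0,
    min_days: int = 300,
) -> PeriodPhenology:
    """Mean phenology over a range of years, excluding low-coverage years."""
    rows, excluded = [], []
    for y in years:
        ph = ice_phenology(series, int(y), threshold_free, threshold_high, min_days)
        if ph.low_coverage:
            excluded.append(int(y))
        else:
            rows.append(ph.as_series())
    if not rows:
        raise ValueError("no qualifying years in the requested period")
    per_year = pd.DataFrame(rows).set_index("year")
    mean = per_year.drop(columns="low_coverage").mean()
    return PeriodPhenology(mean=mean, per_year=per_year, excluded_years=excluded)


def stack_stations(stations: list[StationSeries], min_stations: int = 2) -> StationSeries:
    """Blend stations by daily averaging.

    For each day, the blended mean (and max) temperature is the average over
    the stations reporting that day; days with fewer than ``min_stations``
    reporting are missing.
    """
    if not stations:
        raise ValueError("no stations supplied")
    tmean = pd.concat([s.tmean for s in stations], axis=1)
    tmax = pd.concat([s.tmax for s in stations], axis=1)
    out_mean = tmean.mean(axis=1)
    out_max = tmax.mean(axis=1)
    n_mean = tmean.notna().sum(axis=1)
    n_max = tmax.notna().sum(axis=1)
    out_mean[n_mean < min_stations] = np.nan
    out_max[n_max < min_stations] = np.nan
    return StationSeries(
        name="blended",
        tmean=out_mean.sort_index(),
        tmax=out_max.sort_index(),
        metadata={"stations": [s.name for s in stations], "min_stations": min_stations},
    )


def site_temperature(
    blended: StationSeries, offset: float = -1.6, offset_sigma: float = 0.5
) -> StationSeries:
    """Shift a blended record to the study site by a constant daily offset.

    The default −1.6 °C moves the stack to a colder coastal site; the offset
    uncertainty (default 0.5 °C) is carried as metadata only.
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    return StationSeries(
        name=f"{blended.name}+site_offset",
        tmean=blended.tmean + offset,
        tmax=blended.tmax + offset,
        metadata={**blended.metadata, "offset_c": offset, "offset_sigma_c": offset_sigma},
    )


def melting_season_length(station: StationSeries, year: int) -> tuple[int, float]:
    """Days in a calendar year with daily maximum temperature above 0 °C.

    Returns ``(days, coverage_fraction)``; missing days are excluded from
    the count.
    """
    sel = station.tmax.loc[f"{year}-01-01":f"{year}-12-31"].dropna()
    days_in_year = pd.Timestamp(year=year, month=12, day=31).dayofyear
    return int((sel > 0.0).sum()), len(sel) / days_in_year


def annual_series(daily: pd.Series, how: str = "mean", min_days: int = 300) -> pd.Series:
    """Annual aggregate of a daily series; years with too few days are NaN."""
    daily = _check_daily(daily)
    g = daily.groupby(daily.index.year)
    agg = g.mean() if how == "mean" else g.agg(how)
    agg[g.count() < min_days] = np.nan
    agg.index.name = "year"
    return agg


def linear_trend(annual, values=None) -> TrendEstimate:
    """OLS trend of annual values on year, per decade.

    Accepts a year-indexed Series, a list of (year, value) pairs, or two
    arrays.  Missing values are dropped.  Requires >= 10 years; p-value is
    the two-sided t test with n−2 degrees of freedom.
    """
    if values is not None:
        years = np.asarray(annual, dtype=float)
        vals = np.asarray(values, dtype=float)
    elif isinstance(annual, pd.Series):
        years = annual.index.to_numpy(dtype=float)
        vals = annual.to_numpy(dtype=float)
    else:
        arr = np.asarray(list(annual), dtype=float)
        years, vals = arr[:, 0], arr[:, 1]
    ok = np.isfinite(years) & np.isfinite(vals)
    years, vals = years[ok], vals[ok]
    if years.size < 10:
        raise ValueError("trend estimation needs at least 10 years")
    if np.ptp(years) == 0:
        raise ValueError("all observations share one year; slope undefined")
    res = stats.linregress(years, vals)
    return TrendEstimate(
        slope_per_decade=10.0 * res.slope,
        slope_se=10.0 * res.stderr,
        r_squared=res.rvalue**2,
        p_value=res.pvalue,
        n_years=int(years.size),
        intercept=res.intercept,
    )
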