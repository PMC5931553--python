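"""End-to-end orchestration of the sediment-record analysis stages.

Reads the CSV input dialects, runs chronology → proxies → zonation →
climate, and writes per-stage tables plus a machine-readable summary.  All
randomness funnels through the config seed, and outputs are written with
fixed float formats so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chronology as chron
from . import climate as clim
from . import proxies as prox
from . import zonation as zon

__all__ = ["PipelineConfig", "StageError", "run_chronology", "run_proxies",
           "run_zones", "run_seaice", "run_temperature", "run_all"]

log = logging.getLogger("arclake")

_FLOAT_FMT = "%.6g"
SUMMARY_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    # inputs
    isotope_csv: str | None = None
    counts_csv: str | None = None
    loi_csv: str | None = None
    sic_csv: str | None = None
    station_csv: str | None = None
    bomb_curve_csv: str | None = None
    radiocarbon: dict | None = None  # {f14c_percent, f14c_sigma, delta13c, depth_cm}
    # chronology
    collection_year: float = 2015.0
    core_area_cm2: float = 1.0
    decay_constant: float = chron.PB210_DECAY_CONSTANT
    monte_carlo_n: int = 1000
    crs_reference_cs: bool = True  # use the 137Cs peak as the CRS reference horizon
    c14_tie_age: float = 1973.0
    c14_tie_sigma: float = 2.0
    # proxies / zonation
    count_group: str | None = None
    exclude_taxa: tuple = ()
    max_splits: int | None = 8
    transform: str | None = None  # None or "sqrt"
    # climate
    threshold_free: float = 55.0
    threshold_high: float = 75.0
    site_offset_c: float = -1.6
    site_offset_sigma_c: float = 0.5
    min_stations: int = 2
    region: dict | None = None
    # run control
    seed: int = 0
    outdir: str = "arclake_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_taxa" in raw and raw["exclude_taxa"] is not None:
            raw["exclude_taxa"] = tuple(raw["exclude_taxa"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    manifest = {"config_hash": config.hash(), "schema_version": SUMMARY_SCHEMA_VERSION}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_chronology(config: PipelineConfig) -> chron.AgeDepthModel:
    """Chronology stage: excess 210Pb, CRS ages, tie points, quadratic fit."""
    out = _outdir(config)
    _write_manifest(config, out)
    try:
        if not config.isotope_csv:
            raise ValueError("isotope_csv not configured")
        profile = chron.IsotopeProfile.from_csv(config.isotope_csv)
        excess = chron.excess_pb210(profile, core_area_cm2=config.core_area_cm2)
        _write_csv(excess.to_frame(), out / "excess_pb.csv")
        if excess.clamped.any():
            log.warning("chronology: clamped %d negative excess value(s)",
                        int(excess.clamped.sum()))

        cs = chron.detect_cs137_peak(profile)
        ties = chron.crs_ages(
            excess,
            collection_year=config.collection_year,
            decay_constant=config.decay_constant,
            n_monte_carlo=config.monte_carlo_n,
            seed=config.seed,
            reference=cs.tie if config.crs_reference_cs else None,
        )
        n_excluded = excess.n_slices - len(ties)
        if n_excluded:
            log.info("chronology: %d deep horizon(s) below the 5%% inventory "
                     "cutoff excluded from CRS", n_excluded)

        ties = ties + [cs.tie]
        if config.radiocarbon and config.bomb_curve_csv:
            sample = chron.RadiocarbonSample(
                f14c_percent=config.radiocarbon["f14c_percent"],
                f14c_sigma=config.radiocarbon["f14c_sigma"],
                delta13c=config.radiocarbon.get("delta13c", float("nan")),
                depth=config.radiocarbon["depth_cm"],
            )
            curve = pd.read_csv(config.bomb_curve_csv)
            intervals = chron.calibrate_bomb_14c(sample, curve)
            log.info("chronology: bomb-14C intervals %s", intervals)
            ties.append(chron.TiePoint(sample.depth, config.c14_tie_age,
                                       config.c14_tie_sigma, "c14_bomb"))

        model = chron.fit_age_depth(
            ties,
            collection_year=config.collection_year,
            max_depth=float(profile.depth_bottom[-1]),
        )
        tie_df = pd.DataFrame(
            {
                "depth_cm": [p.depth for p in model.fit_points],
                "age_ad": [p.age for p in model.fit_points],
                "age_sd": [p.age_sigma for p in model.fit_points],
                "source": [p.source for p in model.fit_points],
            }
        )
        _write_csv(tie_df, out / "tie_points.csv")
        _write_csv(model.to_frame(), out / "age_model.csv")
        (out / "chronology.json").write_text(json.dumps(
            {
                "poly_coefficients": [model.a, model.b, model.c],
                "total_inventory_bq_cm2": excess.total_inventory,
                "tail_inventory_bq_cm2": excess.tail_inventory,
                "cs137_peak_depth_cm": cs.tie.depth,
                "cs137_half_max_window_cm": [cs.window_top, cs.window_bottom],
                "config_hash": config.hash(),
            }, sort_keys=True, indent=1))
        return model
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage tag
        raise StageError("chronology", exc) from exc


def run_proxies(config: PipelineConfig, model: chron.AgeDepthModel | None = None):
    """Proxy stage: concentrations, relative abundances, LOI, ages."""
    out = _outdir(config)
    try:
        if not config.counts_csv:
            raise ValueError("counts_csv not configured")
        table = prox.CountTable.from_csv(config.counts_csv, group=config.count_group)
        ages = None
        if model is not None:
            in_range = table.depths <= model.depth_range[1]
            if not in_range.all():
                log.warning("proxies: %d sample(s) below the age-model range "
                            "left undated", int((~in_range).sum()))
            ages = np.full(table.n_samples, np.nan)
            ages[in_range] = prox.assign_ages(model, table.depths[in_range])

        conc_total, conc_sig = prox.marker_concentration(table)
        conc = pd.DataFrame({"depth_cm": table.depths})
        if ages is not None:
            conc["age_ad"] = ages
        conc["total_per_g"] = conc_total
        conc["total_per_g_sd"] = conc_sig
        for taxon in table.taxa:
            c, s = prox.marker_concentration(table, taxon)
            conc[f"{taxon}_per_g"] = c
        _write_csv(conc, out / "concentrations.csv")

        matrix = prox.relative_abundance(table, exclude=config.exclude_taxa, ages=ages)
        _write_csv(matrix.to_frame(), out / "relative_abundance.csv")

        if config.loi_csv:
            loi = prox.loi550_series(pd.read_csv(config.loi_csv))
            if model is not None:
                ok = loi["depth_cm"] <= model.depth_range[1]
                loi["age_ad"] = np.nan
                loi.loc[ok, "age_ad"] = prox.assign_ages(model, loi.loc[ok, "depth_cm"].to_numpy())
            _write_csv(loi, out / "loi.csv")
        return matrix
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("proxies", exc) from exc


def run_zones(config: PipelineConfig, matrix: zon.AssemblageMatrix | None = None) -> zon.ZonationResult:
    """Zonation stage on the relative-abundance matrix."""
    out = _outdir(config)
    try:
        if matrix is None:
            path = out / "relative_abundance.csv"
            if not path.exists():
                raise FileNotFoundError("no assemblage matrix; run the proxy stage first")
            matrix = zon.AssemblageMatrix.from_frame(pd.read_csv(path))
        transform = np.sqrt if config.transform == "sqrt" else None
        result = zon.recursive_zonation(matrix, max_splits=config.max_splits,
                                        transform=transform)
        _write_csv(result.to_frame(), out / "zones.csv")
        return result
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("zonation", exc) from exc


def _read_sic(path) -> pd.Series:
    df = pd.read_csv(path)
    if "cell_id" in df.columns:
        return clim.regional_mean_sic(df)
    if not {"date", "sic_percent"} <= set(df.columns):
        raise ValueError("SIC table needs columns date, sic_percent "
                         "(plus cell_id for gridded long format)")
    s = pd.Series(df["sic_percent"].to_numpy(),
                  index=pd.to_datetime(df["date"]), name="sic_percent")
    return s.sort_index()


def run_seaice(config: PipelineConfig) -> pd.DataFrame:
    """Sea-ice stage: annual phenology table and onset trends."""
    out = _outdir(config)
    try:
        if not config.sic_csv:
            raise ValueError("sic_csv not configured")
        series = _read_sic(config.sic_csv)
        if config.region and "cells" not in config.region:
            log.info("seaice: region box ignored for pre-aggregated input")
        years = range(series.index[0].year, series.index[-1].year + 1)
        period = clim.period_phenology(series, years,
                                       threshold_free=config.threshold_free,
                                       threshold_high=config.threshold_high)
        per_year = period.per_year.reset_index()
        _write_csv(per_year, out / "sea_ice_phenology.csv")

        trends = {}
        for col in ("ice_free_days", "high_ice_days", "melt_onset_doy", "freeze_onset_doy"):
            try:
                t = clim.linear_trend(per_year["year"], per_year[col])
            except ValueError:
                continue
            trends[col] = dataclasses.asdict(t)
        (out / "sea_ice_trends.json").write_text(
            json.dumps(trends, sort_keys=True, indent=1))
        return per_year
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("seaice", exc) from exc


def run_temperature(config: PipelineConfig) -> pd.DataFrame:
    """Temperature stage: stack stations, shift to site, melting season."""
    out = _outdir(config)
    try:
        if not config.station_csv:
            raise ValueError("station_csv not configured")
        df = pd.read_csv(config.station_csv, parse_dates=["date"])
        need = {"date", "station", "tmean_c", "tmax_c"}
        if not need <= set(df.columns):
            raise ValueError(f"station table needs columns {sorted(need)}")
        stations = []
        for name, g in df.groupby("station"):
            g = g.sort_values("date").set_index("date")
            stations.append(clim.StationSeries(str(name), g["tmean_c"], g["tmax_c"]))
        blended = clim.stack_stations(stations, min_stations=config.min_stations)
        site = clim.site_temperature(blended, offset=config.site_offset_c,
                                     offset_sigma=config.site_offset_sigma_c)

        years = range(site.tmean.index[0].year, site.tmean.index[-1].year + 1)
        rows = []
        for y in years:
            melt_days, cov = clim.melting_season_length(site, y)
            rows.append({"year": y, "melting_season_days": melt_days,
                         "coverage_fraction": cov})
        annual = pd.DataFrame(rows)
        tmean_annual = clim.annual_series(site.tmean)
        annual = annual.merge(
            tmean_annual.rename("tmean_annual_c").reset_index(), on="year", how="left")
        _write_csv(annual, out / "site_temperature_annual.csv")

        trends = {}
        ok = annual["coverage_fraction"] >= 300 / 366
        try:
            trends["tmean_annual_c"] = dataclasses.asdict(
                clim.linear_trend(annual.loc[ok, "year"], annual.loc[ok, "tmean_annual_c"]))
            trends["melting_season_days"] = dataclasses.asdict(
                clim.linear_trend(annual.loc[ok, "year"], annual.loc[ok, "melting_season_days"]))
        except ValueError:
            pass
        (out / "temperature_trends.json").write_text(
            json.dumps(trends, sort_keys=True, indent=1))
        return annual
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("temperature", exc) from exc


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage and write a machine-readable summary.

    Stage order: chronology → proxies → zonation → sea ice → temperature.
    A stage failure aborts the run (stage-tagged), but outputs of completed
    stages remain on disk.
    """
    out = _outdir(config)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "config_hash": config.hash()}

    model = run_chronology(config)
    summary["chronology"] = {
        "age_at_bottom_ad": model.age_at(model.depth_range[1]),
        "surface_rate_cm_yr": model.sedimentation_rate(0.0),
        "bottom_rate_cm_yr": model.sedimentation_rate(model.depth_range[1]),
        "poly_coefficients": [model.a, model.b, model.c],
    }

    matrix = run_proxies(config, model)
    zres = run_zones(config, matrix)
    summary["zonation"] = {
        "n_significant": zres.n_significant,
        "boundary_depths_cm": [s.boundary_depth for s in zres.splits if s.significant],
        "boundary_ages_ad": [s.boundary_age for s in zres.splits if s.significant],
    }

    if config.sic_csv:
        per_year = run_seaice(config)
        trends = json.loads((out / "sea_ice_trends.json").read_text())
        early = per_year.head(10)["ice_free_days"].mean()
        late = per_year.tail(5)["ice_free_days"].mean()
        summary["sea_ice"] = {
            "ice_free_days_first_decade": early,
            "ice_free_days_last_pentad": late,
            "trends_per_decade": {k: v["slope_per_decade"] for k, v in trends.items()},
        }
    if config.station_csv:
        run_temperature(config)
        trends = json.loads((out / "temperature_trends.json").read_text())
        summary["temperature"] = {
            "trends_per_decade": {k: v["slope_per_decade"] for k, v in trends.items()},
        }

    # stratigraphic-diagram table: age vs proxies vs zones
    strat = pd.read_csv(out / "relative_abundance.csv")
    conc = pd.read_csv(out / "concentrations.csv")
    strat = strat.merge(conc[["depth_cm", "total_per_g"]], on="depth_cm", how="left")
    zone_ids = np.zeros(len(strat), dtype=int)
    for b in sorted(s.position for s in zres.splits if s.significant):
        zone_ids[b:] += 1
    strat["zone"] = zone_ids
    _write_csv(strat, out / "stratigraphic_table.csv")

    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary
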