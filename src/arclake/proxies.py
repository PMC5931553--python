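"""Microfossil concentrations, relative abundances and organic content.

Absolute concentrations rest on the exotic-marker spike: a known number of
foreign particles (Lycopodium spores for pollen/Pediastrum, microspheres
for diatoms) is added to a weighed subsample, so that

    concentration = (taxon_count / marker_counted) * marker_added / dry_mass

in specimens per gram dry sediment.  Counting errors are treated as Poisson
on both counts and propagated by the delta method.  Organic content comes
from loss on ignition: percent weight lost between drying at 105 °C and
ashing at 550 °C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronology import AgeDepthModel
from .zonation import AssemblageMatrix

__all__ = [
    "CountTable",
    "LoiRecord",
    "marker_concentration",
    "relative_abundance",
    "loi550",
    "assign_ages",
]


@dataclass
class CountTable:
    """Taxon counts for a set of samples of one microfossil group.

    ``counts`` is a samples × taxa integer DataFrame; ``marker_counted``,
    ``marker_added`` and ``dry_mass`` (g) are per-sample spike metadata.
    Samples are ordered shallow to deep.
    """

    depths: np.ndarray
    counts: pd.DataFrame
    marker_counted: np.ndarray
    marker_added: np.ndarray
    dry_mass: np.ndarray
    group: str = "diatom"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.marker_counted = np.asarray(self.marker_counted, dtype=float)
        self.marker_added = np.asarray(self.marker_added, dtype=float)
        self.dry_mass = np.asarray(self.dry_mass, dtype=float)
        n = self.depths.size
        if len(self.counts) != n:
            raise ValueError("counts rows must match depths")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("samples must be strictly ordered by depth")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("taxon counts must be non-negative")
        if np.any(self.marker_added <= 0):
            raise ValueError("marker_added must be positive")
        if np.any(self.dry_mass <= 0):
            raise ValueError("dry_mass must be positive")

    @property
    def n_samples(self) -> int:
        return self.depths.size

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format CSV dialect: one row per (sample, taxon)."""
        rows = []
        for i in range(self.n_samples):
            for taxon in self.taxa:
                rows.append(
                    {
                        "depth_cm": self.depths[i],
                        "group": self.group,
                        "taxon": taxon,
                        "count": int(self.counts.iloc[i][taxon]),
                        "marker_counted": self.marker_counted[i],
                        "marker_added": self.marker_added[i],
                        "dry_mass_g": self.dry_mass[i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, group: str | None = None) -> "CountTable":
        need = {"depth_cm", "taxon", "count", "marker_counted", "marker_added", "dry_mass_g"}
        missing = sorted(need - set(df.columns))
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if group is not None and "group" in df.columns:
            df = df[df["group"] == group]
        if df.empty:
            raise ValueError("count table has no rows" + (f" for group {group!r}" if group else ""))
        wide = df.pivot_table(
            index="depth_cm", columns="taxon", values="count", aggfunc="sum", fill_value=0
        ).sort_index()
        meta = df.groupby("depth_cm")[["marker_counted", "marker_added", "dry_mass_g"]].first()
        meta = meta.loc[wide.index]
        return cls(
            depths=wide.index.to_numpy(dtype=float),
            counts=wide.reset_index(drop=True),
            marker_counted=meta["marker_counted"].to_numpy(dtype=float),
            marker_added=meta["marker_added"].to_numpy(dtype=float),
            dry_mass=meta["dry_mass_g"].to_numpy(dtype=float),
            group=group or (df["group"].iloc[0] if "group" in df.columns else "diatom"),
        )

    @classmethod
    def from_csv(cls, path, group: str | None = None) -> "CountTable":
        return cls.from_long_frame(pd.read_csv(path), group=group)


@dataclass(frozen=True)
class LoiRecord:
    """Dry (105 °C) and ashed (550 °C, 4 h) weights of one sample, in grams."""

    depth: float
    dry_weight: float
    ashed_weight: float

    def __post_init__(self) -> None:
        if not 0 < self.ashed_weight <= self.dry_weight:
            raise ValueError("need 0 < ashed_weight <= dry_weight (weighing error?)")


def marker_concentration(
    table: CountTable, taxon: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration (count per g dry sediment) of one taxon or the group total.

    Returns ``(concentration, sigma)`` arrays over samples.  The relative
    variance is Poisson on both the taxon count n and the marker count m:
    ``var = conc^2 * (1/n + 1/m)`` (zero where n = 0).  Raises where no
    markers were counted, since the concentration is then undefined.
    """
    if np.any(table.marker_counted <= 0):
        raise ValueError("marker_counted is zero for some sample; concentration undefined")
    if taxon is None:
        n = table.counts.sum(axis=1).to_numpy(dtype=float)
    else:
        if taxon not in table.counts.columns:
            raise KeyError(f"unknown taxon {taxon!r}")
        n = table.counts[taxon].to_numpy(dtype=float)
    m = table.marker_counted
    conc = (n / m) * table.marker_added / table.dry_mass
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_var = np.where(n > 0, 1.0 / np.where(n > 0, n, 1.0) + 1.0 / m, 0.0)
    sigma = conc * np.sqrt(rel_var)
    return conc, sigma


def relative_abundance(
    table: CountTable,
    include: list[str] | None = None,
    exclude: tuple[str, ...] | list[str] = (),
    low_count_threshold: int = 50,
    ages: np.ndarray | None = None,
) -> AssemblageMatrix:
    """Per-sample taxon proportions under a sum rule.

    The sum rule selects which taxa enter the denominator: ``include``
    restricts to the listed taxa, ``exclude`` removes taxa (e.g. aquatic
    pollen from a terrestrial pollen sum).  Samples whose selected total is
    below ``low_count_threshold`` are flagged ``low_count`` but retained.
    A zero-sum sample is an error.
    """
    taxa = include if include is not None else [t for t in table.taxa if t not in set(exclude)]
    if not taxa:
        raise ValueError("sum rule leaves no taxa")
    sub = table.counts[taxa].to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.depths[totals <= 0]
        raise ValueError(f"zero-sum sample(s) under the sum rule at depths {bad}")
    props = sub / totals[:, None]
    return AssemblageMatrix(
        proportions=props,
        depths=table.depths,
        taxa=list(taxa),
        ages=ages,
        low_count=totals < low_count_threshold,
    )


def loi550(record: LoiRecord) -> float:
    """Loss on ignition, percent: 100 * (dry - ashed) / dry."""
    return 100.0 * (record.dry_weight - record.ashed_weight) / record.dry_weight


def loi550_series(df: pd.DataFrame) -> pd.DataFrame:
    """LOI for a table with columns ``depth_cm, dry_g, ashed_g``."""
    for col in ("depth_cm", "dry_g", "ashed_g"):
        if col not in df.columns:
            raise ValueError(f"LOI table missing column {col!r}")
    out = df.copy()
    out["loi_percent"] = [
        loi550(LoiRecord(r.depth_cm, r.dry_g, r.ashed_g)) for r in df.itertuples()
    ]
    return out[["depth_cm", "loi_percent"]]


def assign_ages(model: AgeDepthModel, depths) -> np.ndarray:
    """Calendar ages (yr AD) for sample depths from an age-depth model."""
    d = np.asarray(depths, dtype=float)
    return model.age_at(d)
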