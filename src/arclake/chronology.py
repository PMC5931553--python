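"""Radiometric chronology for lake-sediment cores.

Implements the constant-rate-of-supply (CRS) lead-210 dating model, bomb-peak
caesium-137 and radiocarbon tie points, and a second-order polynomial
age-depth model with derived sedimentation rates.

The CRS model assumes a constant atmospheric flux of unsupported (excess)
210Pb to the sediment surface.  If ``A(0)`` is the total excess-210Pb
inventory of the core (Bq/cm^2) and ``A(z)`` the inventory below depth ``z``,
the time since deposition of the horizon at ``z`` is

    t(z) = (1/lambda) * ln(A(0) / A(z)),

with ``lambda`` the 210Pb decay constant.  Excess activity is obtained by
subtracting the 226Ra-supported component from total 210Pb, slice by slice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PB210_HALF_LIFE_YR",
    "PB210_DECAY_CONSTANT",
    "IsotopeProfile",
    "ExcessPbProfile",
    "TiePoint",
    "Cs137Peak",
    "RadiocarbonSample",
    "AgeDepthModel",
    "NonMonotoneAgeModelError",
    "excess_pb210",
    "crs_age",
    "crs_ages",
    "detect_cs137_peak",
    "calibrate_bomb_14c",
    "fit_age_depth",
    "sedimentation_rate",
]

#: 210Pb half-life in years (standard value used by the CRS literature).
PB210_HALF_LIFE_YR = 22.3
#: 210Pb decay constant, ln(2) / half-life, in 1/yr.
PB210_DECAY_CONSTANT = math.log(2.0) / PB210_HALF_LIFE_YR

_ISOTOPE_COLUMNS = [
    "depth_top_cm",
    "depth_bottom_cm",
    "dry_mass_g",
    "pb210_bq_kg",
    "pb210_sd",
    "ra226_bq_kg",
    "ra226_sd",
    "cs137_bq_kg",
    "cs137_sd",
]


class NonMonotoneAgeModelError(ValueError):
    """Fitted age-depth polynomial is not strictly decreasing with depth."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class IsotopeProfile:
    """Per-slice radiometric activities of a sediment core.

    Depths are cm below the sediment-water interface, positive downward;
    each slice occupies the half-open interval ``[depth_top, depth_bottom)``.
    Activities are Bq/kg dry sediment with 1-sigma uncertainties; ``NaN``
    marks an unmeasured slice.
    """

    depth_top: np.ndarray
    depth_bottom: np.ndarray
    dry_mass: np.ndarray
    pb210: np.ndarray
    pb210_sigma: np.ndarray
    ra226: np.ndarray
    ra226_sigma: np.ndarray
    cs137: np.ndarray
    cs137_sigma: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "depth_top",
            "depth_bottom",
            "dry_mass",
            "pb210",
            "pb210_sigma",
            "ra226",
            "ra226_sigma",
            "cs137",
            "cs137_sigma",
        ):
            setattr(self, name, _as_float_array(getattr(self, name)))
        n = self.depth_top.size
        if any(getattr(self, f).size != n for f in ("depth_bottom", "dry_mass")):
            raise ValueError("isotope profile fields must have equal length")
        if np.any(self.depth_bottom <= self.depth_top):
            raise ValueError("slice bottoms must lie below slice tops")
        if np.any(np.diff(self.depth_top) <= 0) or np.any(
            self.depth_top[1:] < self.depth_bottom[:-1] - 1e-9
        ):
            raise ValueError("slices must be sorted shallow to deep, non-overlapping")
        if np.any(~np.isnan(self.dry_mass) & (self.dry_mass <= 0)):
            raise ValueError("dry masses must be positive")
        for name in ("pb210", "ra226", "cs137"):
            a = getattr(self, name)
            if np.any(~np.isnan(a) & (a < 0)):
                raise ValueError(f"{name} activities must be non-negative")
            s = getattr(self, name + "_sigma")
            if np.any(~np.isnan(s) & (s < 0)):
                raise ValueError(f"{name} sigmas must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.depth_top.size

    @property
    def depth_mid(self) -> np.ndarray:
        return 0.5 * (self.depth_top + self.depth_bottom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_top_cm": self.depth_top,
                "depth_bottom_cm": self.depth_bottom,
                "dry_mass_g": self.dry_mass,
                "pb210_bq_kg": self.pb210,
                "pb210_sd": self.pb210_sigma,
                "ra226_bq_kg": self.ra226,
                "ra226_sd": self.ra226_sigma,
                "cs137_bq_kg": self.cs137,
                "cs137_sd": self.cs137_sigma,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IsotopeProfile":
        missing = [c for c in _ISOTOPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"isotope table missing columns: {missing}")
        return cls(
            depth_top=df["depth_top_cm"],
            depth_bottom=df["depth_bottom_cm"],
            dry_mass=df["dry_mass_g"],
            pb210=df["pb210_bq_kg"],
            pb210_sigma=df["pb210_sd"],
            ra226=df["ra226_bq_kg"],
            ra226_sigma=df["ra226_sd"],
            cs137=df["cs137_bq_kg"],
            cs137_sigma=df["cs137_sd"],
        )

    @classmethod
    def from_csv(cls, path) -> "IsotopeProfile":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class ExcessPbProfile:
    """Excess (unsupported) 210Pb per slice with cumulative inventories.

    ``inventory_below[k]`` is the excess-210Pb inventory (Bq/cm^2) below the
    *bottom* boundary of slice ``k``, including the extrapolated tail below
    the deepest slice; ``total_inventory`` is the inventory below the
    sediment surface, A(0).
    """

    depth_top: np.ndarray
    depth_bottom: np.ndarray
    depth_mid: np.ndarray
    excess: np.ndarray            # Bq/kg
    excess_sigma: np.ndarray      # Bq/kg
    slice_mass: np.ndarray        # g/cm^2
    cumulative_mass: np.ndarray   # g/cm^2 above slice bottom
    slice_inventory: np.ndarray   # Bq/cm^2
    inventory_below: np.ndarray   # Bq/cm^2, below slice bottom
    total_inventory: float        # Bq/cm^2, A(0)
    tail_inventory: float         # Bq/cm^2 below the deepest slice
    clamped: np.ndarray           # negative excess clamped to zero
    interpolated: np.ndarray      # activity filled in from neighbours
    core_area_cm2: float = 1.0

    @property
    def n_slices(self) -> int:
        return self.excess.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_top_cm": self.depth_top,
                "depth_bottom_cm": self.depth_bottom,
                "excess_bq_kg": self.excess,
                "excess_sd": self.excess_sigma,
                "cumulative_mass_g_cm2": self.cumulative_mass,
                "inventory_below_bq_cm2": self.inventory_below,
                "clamped": self.clamped,
                "interpolated": self.interpolated,
            }
        )


@dataclass(frozen=True)
class TiePoint:
    """A dated horizon: depth (cm), calendar age (yr AD) and its 1-sigma."""

    depth: float
    age: float
    age_sigma: float
    source: str  # one of {"crs", "cs_peak", "c14_bomb", "surface"}

    def __post_init__(self) -> None:
        if self.age_sigma < 0:
            raise ValueError("age_sigma must be non-negative")
        if self.source not in {"crs", "cs_peak", "c14_bomb", "surface"}:
            raise ValueError(f"unknown tie-point source {self.source!r}")


@dataclass(frozen=True)
class Cs137Peak:
    """Located 137Cs activity maximum with its half-maximum depth window."""

    tie: TiePoint
    window_top: float
    window_bottom: float
    interior_peak: bool


@dataclass(frozen=True)
class RadiocarbonSample:
    """Post-bomb radiocarbon measurement (F14C as percent of modern)."""

    f14c_percent: float
    f14c_sigma: float
    delta13c: float
    depth: float

    def __post_init__(self) -> None:
        if self.f14c_percent <= 0:
            raise ValueError("F14C must be positive")


def excess_pb210(
    profile: IsotopeProfile,
    core_area_cm2: float = 1.0,
    tail: str = "exponential",
) -> ExcessPbProfile:
    """Compute excess 210Pb and cumulative inventories from an isotope profile.

    Excess activity is total 210Pb minus the per-slice 226Ra-supported level,
    with uncertainties combined in quadrature.  Negative excess values are
    clamped to zero and flagged.  Slices without a 210Pb/226Ra measurement
    get their excess activity linearly interpolated on cumulative dry mass
    between the bracketing measured slices (the usual treatment when the
    gamma-counting resolution is coarser than the slicing).

    Inventories are integrated from each slice bottom to the core bottom,
    plus an exponential tail below the deepest measured slice fitted to the
    deepest three positive excess activities versus cumulative mass (``tail=
    "exponential"``; ``tail="none"`` disables the correction).

    Parameters
    ----------
    profile:
        Per-slice activities; at least three slices must have both 210Pb and
        226Ra measured.
    core_area_cm2:
        Cross-sectional area used to convert slice dry mass to mass per unit
        area.  The CRS ages depend only on inventory ratios, so the area
        cancels there; it only scales absolute inventories.
    """
    if core_area_cm2 <= 0:
        raise ValueError("core_area_cm2 must be positive")
    if tail not in {"exponential", "none"}:
        raise ValueError("tail must be 'exponential' or 'none'")
    measured = ~np.isnan(profile.pb210) & ~np.isnan(profile.ra226)
    if measured.sum() < 3:
        raise ValueError("need 210Pb and 226Ra on at least 3 slices")
    if np.any(np.isnan(profile.dry_mass)) or np.any(profile.dry_mass <= 0):
        raise ValueError("all slices need positive dry mass")

    slice_mass = profile.dry_mass / core_area_cm2  # g/cm^2
    cum_mass = np.cumsum(slice_mass)               # to slice bottom
    mid_mass = cum_mass - 0.5 * slice_mass

    excess = profile.pb210 - profile.ra226
    sig = np.sqrt(
        np.where(np.isnan(profile.pb210_sigma), 0.0, profile.pb210_sigma) ** 2
        + np.where(np.isnan(profile.ra226_sigma), 0.0, profile.ra226_sigma) ** 2
    )

    interpolated = ~measured
    if interpolated.any():
        excess = excess.copy()
        excess[interpolated] = np.interp(
            mid_mass[interpolated], mid_mass[measured], excess[measured]
        )
        sig = sig.copy()
        sig[interpolated] = np.interp(
            mid_mass[interpolated], mid_mass[measured], sig[measured]
        )

    clamped = excess < 0
    if clamped.any():
        warnings.warn(
            f"clamped {int(clamped.sum())} negative excess-210Pb value(s) to zero",
            stacklevel=2,
        )
        excess = np.where(clamped, 0.0, excess)

    slice_inventory = excess * (slice_mass / 1000.0)  # Bq/kg * kg/cm^2
    tail_inv = 0.0
    if tail == "exponential":
        tail_inv = _tail_inventory(excess, mid_mass, cum_mass)
    below = tail_inv + np.concatenate(
        [np.cumsum(slice_inventory[::-1])[::-1][1:], [0.0]]
    )
    total = tail_inv + float(slice_inventory.sum())

    return ExcessPbProfile(
        depth_top=profile.depth_top.copy(),
        depth_bottom=profile.depth_bottom.copy(),
        depth_mid=profile.depth_mid,
        excess=excess,
        excess_sigma=sig,
        slice_mass=slice_mass,
        cumulative_mass=cum_mass,
        slice_inventory=slice_inventory,
        inventory_below=below,
        total_inventory=total,
        tail_inventory=tail_inv,
        clamped=clamped,
        interpolated=interpolated,
        core_area_cm2=core_area_cm2,
    )


def _tail_inventory(
    excess: np.ndarray, mid_mass: np.ndarray, cum_mass: np.ndarray, n_fit: int = 3
) -> float:
    """Exponential extrapolation of excess activity below the deepest slice.

    Fits ln(excess) ~ a - beta*m over the deepest ``n_fit`` slices with
    positive excess and integrates the fitted exponential from the bottom
    boundary to infinity.  Returns 0 (with a warning) when the profile does
    not decay with mass, in which case CRS ages near the bottom are biased
    young and should be read with care.
    """
    pos = np.flatnonzero(excess > 0)
    if pos.size < n_fit:
        return 0.0
    idx = pos[-n_fit:]
    m = mid_mass[idx]
    y = np.log(excess[idx])
    slope, intercept = np.polyfit(m, y, 1)
    if slope >= 0:
        warnings.warn(
            "deepest excess activities do not decay; tail inventory set to 0",
            stacklevel=3,
        )
        return 0.0
    beta = -slope
    c_bottom = math.exp(intercept + slope * cum_mass[-1]) / 1000.0  # Bq/g
    return c_bottom / beta


def crs_age(
    total_inventory: float,
    inventory_below,
    decay_constant: float = PB210_DECAY_CONSTANT,
):
    """Time since deposition t(z) = ln(A(0)/A(z)) / lambda, in years.

    Undefined (raises) when the inventory below the horizon is not positive.
    """
    a = np.asarray(inventory_below, dtype=float)
    if total_inventory <= 0:
        raise ValueError("total inventory must be positive")
    if np.any(a <= 0):
        raise ValueError("inventory below horizon must be positive (age undefined)")
    out = np.log(total_inventory / a) / decay_constant
    return float(out) if np.isscalar(inventory_below) else out


def _reference_tail(
    slice_inventory: np.ndarray,
    depth_bottom: np.ndarray,
    ref_depth: float,
    ref_t: float,
    decay_constant: float,
) -> float:
    """Unmeasured deep inventory implied by a reference horizon of known age.

    With S(z) the *measured* inventory below z and T the unknown tail, the
    CRS age of the reference horizon fixes T:
    exp(lambda t_r) = (S(0) + T) / (S(z_r) + T).  Negative solutions (tie
    incompatible with the measured inventory) are clamped to zero.
    """
    s_below = np.concatenate([np.cumsum(slice_inventory[::-1])[::-1][1:], [0.0]])
    s0 = float(slice_inventory.sum())
    bounds = np.concatenate([[0.0], depth_bottom])
    s_at = np.concatenate([[s0], s_below])
    s_r = float(np.interp(ref_depth, bounds, s_at))
    e = math.exp(decay_constant * ref_t)
    return max((s0 - e * s_r) / (e - 1.0), 0.0)


def crs_ages(
    excess: ExcessPbProfile,
    collection_year: float,
    decay_constant: float = PB210_DECAY_CONSTANT,
    n_monte_carlo: int = 1000,
    seed: int | None = 0,
    min_inventory_fraction: float = 0.05,
    reference: TiePoint | tuple[float, float] | None = None,
) -> list[TiePoint]:
    """CRS ages at slice-bottom horizons, with Monte-Carlo uncertainties.

    Horizons where the remaining inventory A(z) is at or below
    ``min_inventory_fraction`` of A(0) (default 5%) are considered unreliable
    and excluded: there the logarithm amplifies inventory errors beyond use.

    ``reference`` is an optional independently dated horizon (a TiePoint or
    ``(depth_cm, age_ad)``), typically the 1963 bomb-fallout 137Cs maximum.
    When given, the unmeasured inventory below the core base is not
    extrapolated from the activity profile but solved from the requirement
    that CRS reproduce the reference age (reference-date CRS).  This is far
    more robust when the accumulation rate varies down-core, where
    exponential activity extrapolation can misjudge the deep inventory badly.

    Uncertainties come from ``n_monte_carlo`` replicates that perturb every
    slice's excess activity by its 1-sigma (and the reference age by its
    sigma, if any), clamp at zero, re-derive the tail and inventories, and
    recompute ages; the reported sigma is the replicate standard deviation.
    With zero measurement sigmas the Monte-Carlo sigma is exactly zero.
    """
    ref_depth = ref_age = ref_sigma = None
    if reference is not None:
        if isinstance(reference, TiePoint):
            ref_depth, ref_age, ref_sigma = reference.depth, reference.age, reference.age_sigma
        else:
            ref_depth, ref_age = float(reference[0]), float(reference[1])
            ref_sigma = 0.0

    def _inventories(excess_act: np.ndarray, ref_age_r) -> tuple[np.ndarray, float]:
        inv = excess_act * (excess.slice_mass / 1000.0)
        if ref_depth is not None:
            tail = _reference_tail(
                inv, excess.depth_bottom, ref_depth,
                collection_year - ref_age_r, decay_constant,
            )
        else:
            mid_mass = excess.cumulative_mass - 0.5 * excess.slice_mass
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tail = _tail_inventory(excess_act, mid_mass, excess.cumulative_mass)
        below = tail + np.concatenate([np.cumsum(inv[::-1])[::-1][1:], [0.0]])
        return below, tail + float(inv.sum())

    if reference is not None:
        below, a0 = _inventories(excess.excess, ref_age)
    else:
        below, a0 = excess.inventory_below, excess.total_inventory
    if a0 <= 0:
        raise ValueError("total excess-210Pb inventory must be positive")
    usable = below > min_inventory_fraction * a0
    if not usable.any():
        raise ValueError("no horizon retains enough inventory for CRS dating")

    t = np.log(a0 / below[usable]) / decay_constant
    depths = excess.depth_bottom[usable]

    sigmas = np.zeros(t.size)
    if n_monte_carlo > 0 and np.any(excess.excess_sigma > 0):
        rng = np.random.default_rng(seed)
        reps = np.empty((n_monte_carlo, t.size))
        for r in range(n_monte_carlo):
            pert = excess.excess + rng.standard_normal(excess.n_slices) * excess.excess_sigma
            pert = np.clip(pert, 0.0, None)
            ref_r = ref_age
            if ref_sigma:
                ref_r = ref_age + rng.standard_normal() * ref_sigma
            below_r, a0_r = _inventories(pert, ref_r)
            b = below_r[usable]
            with np.errstate(divide="ignore", invalid="ignore"):
                reps[r] = np.where(b > 0, np.log(a0_r / b) / decay_constant, np.nan)
        sigmas = np.nanstd(reps, axis=0)
        sigmas = np.where(np.isnan(sigmas), 0.0, sigmas)

    return [
        TiePoint(depth=float(d), age=float(collection_year - ti), age_sigma=float(s), source="crs")
        for d, ti, s in zip(depths, t, sigmas)
    ]


def detect_cs137_peak(
    profile: IsotopeProfile,
    peak_age: float = 1962.5,
    peak_age_sigma: float = 1.0,
) -> Cs137Peak:
    """Locate the bomb-fallout 137Cs activity maximum.

    The slice with the highest 137Cs activity is dated to the 1962-1963
    atmospheric-testing maximum (1962.5 AD by default, sigma 1 yr).  Ties
    break toward the shallower slice.  Also reports the contiguous depth
    window where activity stays at or above half the maximum, and whether
    the maximum is an interior peak (not at the profile's measured ends).
    """
    cs = profile.cs137
    measured = ~np.isnan(cs)
    if measured.sum() < 3:
        raise ValueError("need 137Cs measured at >= 3 depths")
    if np.nanmax(cs) <= 0:
        raise ValueError("no 137Cs signal (all zero or missing)")

    idx = int(np.nanargmax(cs))  # first occurrence -> shallower on ties
    peak_val = cs[idx]
    meas_idx = np.flatnonzero(measured)
    interior = idx != meas_idx[0] and idx != meas_idx[-1]

    half = 0.5 * peak_val
    lo = hi = idx
    while lo - 1 >= 0 and (np.isnan(cs[lo - 1]) or cs[lo - 1] >= half):
        lo -= 1
    while hi + 1 < profile.n_slices and (np.isnan(cs[hi + 1]) or cs[hi + 1] >= half):
        hi += 1

    tie = TiePoint(
        depth=float(profile.depth_mid[idx]),
        age=peak_age,
        age_sigma=peak_age_sigma,
        source="cs_peak",
    )
    return Cs137Peak(
        tie=tie,
        window_top=float(profile.depth_top[lo]),
        window_bottom=float(profile.depth_bottom[hi]),
        interior_peak=bool(interior),
    )


def calibrate_bomb_14c(
    sample: RadiocarbonSample,
    curve: pd.DataFrame,
    k: float = 1.0,
) -> list[tuple[int, int]]:
    """Intersect a post-bomb F14C measurement with a bomb calibration curve.

    ``curve`` must have columns ``year_ad, f14c_percent, f14c_sd``.  Returns
    every maximal run of consecutive curve years where
    ``|sample - curve| <= k * sqrt(sigma_sample^2 + sigma_curve^2)`` as
    inclusive ``(start_year, end_year)`` intervals.  A measurement below the
    bomb peak typically yields two intervals, one on the rising and one on
    the falling limb of the curve.
    """
    for col in ("year_ad", "f14c_percent", "f14c_sd"):
        if col not in curve.columns:
            raise ValueError(f"calibration curve missing column {col!r}")
    if sample.f14c_percent <= 100.0:
        raise ValueError("sample is not post-bomb (F14C <= 100%)")
    cur = curve.sort_values("year_ad")
    years = cur["year_ad"].to_numpy(dtype=float)
    if years.max() < 1955.0:
        raise ValueError("curve does not cover the post-1950 bomb era")
    f = cur["f14c_percent"].to_numpy(dtype=float)
    s = cur["f14c_sd"].to_numpy(dtype=float)
    tol = k * np.sqrt(sample.f14c_sigma**2 + s**2)
    ok = np.abs(sample.f14c_percent - f) <= tol
    if not ok.any():
        raise ValueError("sample never intersects the calibration-curve envelope")

    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((int(years[start]), int(years[i - 1])))
            start = None
    if start is not None:
        intervals.append((int(years[start]), int(years[-1])))
    return intervals


@dataclass
class AgeDepthModel:
    """Quadratic age-depth model ``age(d) = a d^2 + b d + c`` (yr AD, cm).

    Strictly decreasing in depth over ``depth_range`` (checked at fit time
    on a 0.1 cm grid).  Evaluation outside the range raises.
    """

    a: float
    b: float
    c: float
    fit_points: list[TiePoint] = field(default_factory=list)
    depth_range: tuple[float, float] = (0.0, 0.0)
    collection_year: float = float("nan")

    def age_at(self, depth):
        d = np.asarray(depth, dtype=float)
        lo, hi = self.depth_range
        if np.any(d < lo - 1e-9) or np.any(d > hi + 1e-9):
            raise ValueError(f"depth outside model range {self.depth_range}")
        out = self.a * d**2 + self.b * d + self.c
        return float(out) if np.isscalar(depth) else out

    def sedimentation_rate(self, depth):
        """cm/yr from the polynomial derivative: rate = -1 / (2 a d + b)."""
        d = np.asarray(depth, dtype=float)
        lo, hi = self.depth_range
        if np.any(d < lo - 1e-9) or np.any(d > hi + 1e-9):
            raise ValueError(f"depth outside model range {self.depth_range}")
        deriv = 2.0 * self.a * d + self.b
        if np.any(deriv == 0):
            raise ZeroDivisionError("age-depth derivative vanishes within range")
        out = -1.0 / deriv
        return float(out) if np.isscalar(depth) else out

    def to_frame(self, step: float = 0.5) -> pd.DataFrame:
        d = np.arange(self.depth_range[0], self.depth_range[1] + 1e-9, step)
        return pd.DataFrame(
            {
                "depth_cm": d,
                "age_ad": self.age_at(d),
                "sedimentation_rate_cm_yr": self.sedimentation_rate(d),
            }
        )


def fit_age_depth(
    points: list[TiePoint],
    collection_year: float,
    add_surface: bool = True,
    surface_sigma: float = 0.5,
    max_depth: float | None = None,
) -> AgeDepthModel:
    """Weighted least-squares quadratic through tie points.

    A surface tie (0 cm, ``collection_year``, sigma ``surface_sigma``) is
    appended unless one is already present or ``add_surface`` is False.
    Weights are 1/sigma for points with positive sigma, 1 otherwise (so the
    objective weights squared residuals by 1/sigma^2).  The fit is rejected
    if the polynomial is not strictly decreasing on a 0.1 cm grid over the
    depth range, or if a supplied surface point is missed by more than 1 yr.
    """
    pts = list(points)
    if add_surface and not any(p.source == "surface" for p in pts):
        pts.append(TiePoint(0.0, collection_year, surface_sigma, "surface"))
    if len(pts) < 3:
        raise ValueError("need at least 3 tie points for a quadratic fit")
    # ``max_depth`` extends the usable (extrapolated) range below the deepest
    # tie point, e.g. to the core bottom; monotonicity is checked over it.
    d = np.array([p.depth for p in pts])
    y = np.array([p.age for p in pts])
    s = np.array([p.age_sigma for p in pts])
    w = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 1.0)
    a, b, c = np.polyfit(d, y, 2, w=w)

    lo, hi = 0.0, float(max(d.max(), max_depth or 0.0))
    grid = np.arange(lo, hi + 1e-9, 0.1)
    ages = a * grid**2 + b * grid + c
    if not np.all(np.diff(ages) < 0):
        raise NonMonotoneAgeModelError(
            "fitted polynomial is not strictly decreasing with depth "
            "(tie points are mutually incompatible)"
        )
    model = AgeDepthModel(
        a=float(a),
        b=float(b),
        c=float(c),
        fit_points=pts,
        depth_range=(lo, hi),
        collection_year=collection_year,
    )
    if any(p.source == "surface" for p in pts):
        if abs(model.age_at(0.0) - collection_year) > 1.0:
            raise NonMonotoneAgeModelError(
                "fitted model misses the surface age by more than 1 yr"
            )
    return model


def sedimentation_rate(model: AgeDepthModel, depth):
    """Sedimentation rate (cm/yr) at ``depth`` from an age-depth model."""
    return model.sedimentation_rate(depth)
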