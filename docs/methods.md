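# Methods

This note documents the models implemented in `arclake`, the choices made
where the methodology was genuinely open, and what the synthetic generators
do and do not emulate.

## Chronology

### Excess ²¹⁰Pb

Excess (unsupported) activity is total ²¹⁰Pb minus the *per-slice* ²²⁶Ra
value — not a core-wide mean — with uncertainties combined in quadrature.
Negative excess values (possible at depth, where the two activities
converge) are clamped to zero and flagged; inventories must be
non-negative, and the flag preserves auditability.  Slices without a
gamma measurement (typical when counting resolution is coarser than
slicing) get excess interpolated linearly on cumulative dry mass between
bracketing measured slices; interpolated slices are flagged.

Inventories are carried per cm² of core area.  The area cancels in CRS ages
(only inventory ratios enter), so `core_area_cm2` defaults to 1 and only
scales absolute inventories.

### Deep-inventory (tail) treatment

CRS is sensitive to inventory below the deepest measured slice.  Two
estimators are provided:

1. **Exponential extrapolation** (default in `excess_pb210`): fit
   ln(excess) against cumulative mass over the deepest three positive
   slices and integrate the fitted exponential to infinity.  This is exact
   when the deep profile is log-linear in mass — i.e. when the mass
   accumulation rate is locally constant — and our constant-rate and
   two-epoch recovery checks confirm sub-0.1-yr accuracy there.  It fails
   badly, however, when accumulation *slows* down-core: initial activity
   P/r then rises with depth, largely cancelling the decay, the
   activity-versus-mass profile flattens, and the extrapolated tail can
   overshoot by an order of magnitude, biasing every CRS age young.
2. **Reference-date CRS** (`crs_ages(..., reference=...)`): given an
   independently dated horizon (depth z_r, age t_r) — here the 1963 ¹³⁷Cs
   maximum — the tail T is solved from
   exp(λ t_r) = (S(0)+T)/(S(z_r)+T), where S are measured partial
   inventories.  This follows the reference-date variant of the CRS
   recommendations and is robust to arbitrary rate histories; it is the
   pipeline default (`crs_reference_cs: true`).

Ages are evaluated at slice-bottom boundaries, where the discrete inventory
sum is exact for slice-averaged activities.  Horizons retaining ≤ 5% of
A(0) are excluded as unreliable (the logarithm amplifies inventory error
without bound).  Age uncertainties come from Monte-Carlo perturbation of
all excess activities by their 1σ (and the reference age by its σ),
re-deriving tail and inventories in every replicate; 1000 replicates by
default, seeded, and exactly zero σ when measurement σ is zero.

### Tie points and the age model

The ¹³⁷Cs maximum is dated 1962.5 ± 1 AD (midpoint of the 1962–1963
fallout peak); ties break toward the shallower slice, the half-maximum
depth window is reported, and a maximum at the profile edge is flagged as
"no interior peak".  Post-bomb ¹⁴C is calibrated by intersecting the
measurement envelope (k·combined σ, k = 1) with a user-supplied annual
curve; both the rising- and falling-limb intervals are reported, and the
choice between them is left to the other ties (the pipeline default adopts
the falling-limb midpoint, 1973 ± 2 AD, as the tie age).

The age-depth model is a weighted least-squares quadratic through all tie
points (weights 1/σ², unit where σ = 0 is not given) plus a surface tie
(0 cm, collection year, σ = 0.5 yr).  CRS ages and independent ties are fit
jointly by default; fitting CRS ages alone is possible by passing only
those points.  Monotonicity is verified on a 0.1 cm grid; evaluation
outside the fitted range raises, except that the pipeline extends the
range to the core bottom (the usual practice of quoting an extrapolated
basal age).  A supplied surface tie must be reproduced within 1 yr, else
the fit is rejected as internally inconsistent.  Sedimentation rate is the
reciprocal derivative, −1/(2ad + b).

## Proxies

Concentration σ uses Poisson counting error on both the taxon and marker
counts (delta method, relative variance 1/n + 1/m); weighing error is
ignored as negligible against counts of order 20–300.  Counting-stop rules
are lab procedure, not computation: the code accepts whatever counts are
supplied and flags group totals below 50 as low-count while retaining
them.  Sum rules (e.g. excluding aquatic pollen) are expressed as
include/exclude taxon lists supplied by the user.  LOI is
100·(dry − ashed)/dry on 105 °C/550 °C weights; ashed > dry is rejected as
a weighing error.

## Zonation

The information content of a block is the Kullback–Leibler deviance of its
rows from the block mean, in nats.  The method name ("optimal splitting by
information content") admits several variants; this one follows the
classical information-content zonation tradition and is pluggable — the
measure is a single function, and a `transform` hook (e.g. square-root)
is applied to proportions before any information is computed
(untransformed by default).

Splitting is greedy recursive binary: at each step every cut of every
current block is evaluated exhaustively and the globally best reduction is
taken (exact per step).  Greedy order does not guarantee monotonically
decreasing reductions — a child block can expose a stronger internal cut —
so splits are *ranked by reduction* for significance, matching the
broken-stick null, which concerns ordered piece sizes.  The null uses
n_pieces = n_samples (the stick cannot be resolved finer than the
sampling); split rank k is significant while its proportional reduction
exceeds b_k, and `n_significant` is the longest all-significant prefix.
Boundary depths/ages are midpoints between the bracketing samples.

## Climate

The ice-free season is the annual *count* of sub-55% days, not a
last-minus-first crossing — robust to mid-season excursions.  Melt onset is
the first day of the longest sub-threshold run, freeze onset the first day
after it; the source study plots a season without defining an onset rule,
so the longest-run convention is ours.  High-ice days count >75% days.
Years with fewer than 300 valid days are flagged and excluded from period
means (mirroring the partial satellite coverage of the early record).
Regional means over an equal-area grid are unweighted over ocean cells,
with days below 50% cell coverage set missing.

Station stacking averages whichever stations report each day (configurable
minimum); the blend is shifted to the site by a constant daily offset
(−1.6 ± 0.5 °C by default), applied after blending.  Melting-season length
counts Tmax > 0 °C days.  Trends are plain OLS per decade with t-based
standard errors and two-sided p-values, no autocorrelation correction —
matching how such trends are conventionally quoted for annual series.

## Synthetic generators

The generators define the study conditions and carry analytic ground truth.

**Sediment core.**  A prescribed epoch-wise mass-accumulation history with
constant ²¹⁰Pb flux; 1 cm slices (the field slicing protocol); constant dry
bulk density 0.1 g cm⁻³ maps mass to depth (no compaction model — the real
profile is unknown, so dry mass is exposed directly).  Slice activities
are *slice averages* of the analytic inventory integral — exactly what a
gamma measurement of a homogenised slice reports — so zero-noise CRS
recovery is limited only by the tail treatment.  The default history is a
nine-epoch discretisation of a smooth quadratic age-depth relation
(~0.05 cm/yr at the 1900 AD base to ~0.2–0.25 cm/yr at the surface,
≈ 9.6 cm total): the emulated archive is well described by a quadratic, so
the generator's truth must be too, or the model contract would be broken
by construction.  ¹³⁷Cs is a Gaussian pulse in age (σ = 2 yr) centred on
1963, giving the broad depth maximum real profiles show.  Noise is
multiplicative lognormal with unit mean (activities are positive).

**Assemblages.**  Dirichlet-multinomial counts around per-zone
compositions (ten diatom-like taxa by default, dispersion 50, 300 counts
per sample — typical slide totals); marker counts are Poisson with mean
marker_added · counts/(true concentration · dry mass), floored at one so
concentrations stay defined, making the ratio estimator unbiased around
the imposed truth (2·10⁴ per g by default, the scale of the emulated
record).

**Climate.**  SIC follows a trapezoidal seasonal cycle whose melt and
freeze ramps (40-day width) translate independently; the daily value is
the max of the two ramps, so overlapping ramps (short, shallow summers in
the early record) remain well defined and the threshold-crossing window is
analytic in closed form, with imposed onset trends equal to the crossing
trends exactly.  A phase-shifted clipped sinusoid was considered and
rejected: a single phase shift cannot move melt earlier *and* freeze later,
which the emulated asymmetry (20 vs 19 d/decade) requires.  Onset anchors
(melt DOY 170, freeze DOY 257 at 1990) reproduce the emulated ice-free
period means (~100 d in 1988–1997, ~180 d in 2010–2014).  Temperature is a
sinusoidal cycle (amplitude 8 °C, level −5.3 °C, peak DOY 201) plus a
linear trend (0.7 °C/decade), a shared interannual anomaly (σ = 1 °C,
without which annual-mean trend errors would be unrealistically small), a
per-station AR(1) daily anomaly (φ = 0.65, σ = 2.5 °C) and constant
station offsets spanning ~0.7 °C; daily maximum is daily mean + 3 °C.  At
these settings the imposed warming corresponds analytically to a
melting-season lengthening of ~11–12 d/decade at the site.

**What the generators do not emulate:** sediment mixing/bioturbation and
compaction; taphonomy and dissolution of microfossils; spatial SIC
structure (the regional mean is generated directly; gridded inputs are
exercised with simple constructed fields); weather beyond AR(1) daily
persistence; station data gaps.  Passing recovery tests therefore shows
the *estimators* are correct under the stated statistical conditions, not
that real archives satisfy those conditions.

## Problem sizes and numerical choices

Test and acceptance runs use the scales above: ~10–17-slice cores, 20–24
sample assemblages with 10 taxa, 30–56-year daily climate series, 100–200
random seeds for recovery rates, 500–1000 Monte-Carlo replicates for age
uncertainties.  Ties in peak detection and splitting break toward the
shallower slice/cut.  Splitting stops when the best reduction is ≤ 10⁻¹²
nats.  Degenerate inputs raise rather than guess: zero inventory at a
requested horizon, zero-sum samples under a sum rule, ashed > dry weights,
non-monotone tie-point sets, constant-year trend input.

## Known limitations

- The exponential tail estimator is unreliable under strong down-core rate
  slowdown; use the reference-date variant (pipeline default) whenever an
  independent tie exists.  Even then, sub-slice interpolation of the
  reference inventory leaves ~1 yr of error per slice-width of age span at
  the core base.
- A quadratic age-depth model cannot follow histories with abrupt rate
  steps; the fit raises on non-monotonicity but cannot detect smooth
  misfit beyond the surface-tie check.
- The broken-stick significance test is calibrated for assemblages with a
  realistic number of taxa; with very few taxa (≤ 3) its false-positive
  rate rises because the best-split statistic concentrates more of the
  total information.
- Trend inference ignores autocorrelation of annual values; p-values are
  anti-conservative if strong interannual persistence is present.
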