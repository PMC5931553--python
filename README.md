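# arclake

Analysis toolkit for short (~100 yr) Arctic lake-sediment records and the
climate series they are compared against.  It covers the full chain a
palaeolimnological study needs:

- **Radiometric chronology** — excess ²¹⁰Pb from total ²¹⁰Pb and ²²⁶Ra,
  constant-rate-of-supply (CRS) dating with Monte-Carlo uncertainties and an
  optional reference horizon, ¹³⁷Cs bomb-peak detection, post-bomb ¹⁴C
  calibration against a user-supplied curve, and a second-order polynomial
  age-depth model with derived sedimentation rates.
- **Proxy quantification** — absolute microfossil concentrations from an
  exotic-marker spike (*Lycopodium* spores, microspheres), relative
  abundances under configurable sum rules, and loss-on-ignition organic
  content.
- **Stratigraphic zonation** — optimal splitting by information content with
  broken-stick significance.
- **Climate metrics** — regional-mean sea-ice concentration, ice-free and
  high-ice day counts with melt/freeze onsets, stacked-station temperature
  reconstruction with a constant site offset, melting-season length, and
  decadal OLS trends.
- **Synthetic data** — generators for every input class with analytic ground
  truth, so each stage is verifiable by parameter recovery without any
  external download.

## The models in brief

**CRS dating.** Unsupported ²¹⁰Pb reaches the sediment at a constant flux
*P*. With *A*(0) the total excess-²¹⁰Pb inventory (Bq cm⁻²) and *A*(z) the
inventory below depth *z*,

    t(z) = (1/λ) ln[A(0) / A(z)],     λ = ln 2 / 22.3 yr⁻¹,

independently of how the accumulation rate varied. The unmeasured inventory
below the core base is either extrapolated exponentially in cumulative mass
or — more robustly — solved from an independently dated reference horizon
such as the 1963 ¹³⁷Cs maximum.

**Zonation.** For a contiguous block of compositional samples with
proportions *p₍ᵢⱼ₎* and block mean *qⱼ*, the information content is
I = Σᵢ Σⱼ p₍ᵢⱼ₎ ln(p₍ᵢⱼ₎/qⱼ). Recursive binary splitting maximises the
reduction I(block) − I(left) − I(right); split *k* (ranked by reduction) is
significant while its share of I(whole) exceeds the broken-stick expectation
bₖ = (1/n) Σⱼ₌ₖⁿ 1/j.

**Spike concentrations.** With *n* specimens and *m* markers counted, *M*
markers added and *w* g of dry sediment, concentration = (n/m)·M/w, with
Poisson counting error on both counts.

**Climate metrics.** The ice-free season is the annual count of days with
regional-mean SIC < 55%; the melting season is the annual count of days with
daily maximum temperature > 0 °C; trends are OLS slopes of annual values on
year, reported per decade with t-based standard errors and p-values.

## Worked example

```sh
python examples/chronology_crs.py
```

```
total excess-210Pb inventory A(0): 0.486 Bq/cm^2
137Cs maximum at 5.5 cm  (true 1963 horizon: 5.8 cm), dated 1962.5 AD

depth_cm  crs_age_AD  +-1sigma   true_age
    1.0     2009.5      0.3    2009.9
    2.0     2002.9      0.4    2003.4
    3.0     1993.7      0.6    1995.2
    ...
sedimentation rate: 0.26 cm/yr at the surface, 0.04 cm/yr at the base (5.9x acceleration)
```

The synthetic core was built with a known deposition history (5% measurement
noise), so the CRS column can be read directly against the true ages; the
rate ratio recovers the imposed five-fold recent acceleration.  The other
scripts in `examples/` demonstrate zonation, spike concentrations and LOI,
sea-ice phenology, and the stacked-station temperature reconstruction, each
printing the recovered quantities next to the generator's imposed truth.

A complete run over all stages, from CSV inputs to a `summary.json` of
headline numbers (zone-boundary ages, phenology period means, decadal
trends), is available both as a library call (`arclake.pipeline.run_all`)
and as a CLI:

```sh
arclake synth --outdir inputs --seed 7     # write a synthetic input bundle
arclake all --config config.yaml --outdir out --seed 7
```

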