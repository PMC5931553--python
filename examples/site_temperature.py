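"""Reconstruct site temperature from stacked stations and trend the melting season.

Blends several station records by daily averaging, shifts the blend to a
colder coastal site by a constant offset (-1.6 °C), and regresses annual
mean temperature and melting-season length (days with Tmax > 0 °C) on year.
"""

import numpy as np

from arclake.climate import (
    annual_series,
    linear_trend,
    melting_season_length,
    site_temperature,
    stack_stations,
)
from arclake.synthetic import ClimateScenario, gen_daily_climate

scenario = ClimateScenario(seed=3)  # imposed warming: 0.7 C/decade
_, stations, _ = gen_daily_climate(scenario)

blended = stack_stations(stations, min_stations=2)
site = site_temperature(blended, offset=-1.6, offset_sigma=0.5)

tr = linear_trend(annual_series(site.tmean))
print(f"annual mean site temperature trend: {tr.slope_per_decade:+.2f} "
      f"+/- {tr.slope_se:.2f} C/decade (imposed +0.70), R^2 = {tr.r_squared:.2f}")

years = np.array(list(scenario.years))
melt = [melting_season_length(site, y)[0] for y in years]
tr_m = linear_trend(years.astype(float), melt)
print(f"melting season: {melt[0]} days ({years[0]}) -> {melt[-1]} days ({years[-1]})")
print(f"melting-season trend: {tr_m.slope_per_decade:+.1f} +/- {tr_m.slope_se:.1f} "
      f"d/decade, R^2 = {tr_m.r_squared:.2f}, p = {tr_m.p_value:.1e}")
# At this seasonal amplitude and site offset, a 0.7 C/decade warming
# corresponds analytically to ~12 extra above-freezing days per decade;
# single 56-yr realizations scatter around that by 1-2 d/decade.
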