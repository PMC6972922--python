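"""The 18-scenario grid and the pressure arithmetic behind it.

Three climate levels (RCP2.6/4.5/8.5) x three development levels
(1.5/2.0/2.5 %/yr growth) x two precipitation regimes. Tourism growth
compounds into recreational fishing mortality over the 35-year horizon;
the wet high/high cell gains 17.9% wetland/estuary area by 2050.
"""
from marinefutures import (compound_increase, enumerate_scenarios,
                           parse_scenario_id, whole_percent)
from marinefutures.synthetic import generate_terrestrial_drivers

grid = enumerate_scenarios()
print(f"{len(grid)} scenarios:", ", ".join(sc.id for sc in grid[:6]), "...")

for level, rate in (("low", 0.015), ("medium", 0.020), ("high", 0.025)):
    pct = compound_increase(rate, 35)
    print(f"{level:6s} growth {rate:.1%}/yr -> +{pct:6.2f}% over 2015-2050 "
          f"(quoted as {whole_percent(pct)}%)")

ds = generate_terrestrial_drivers(parse_scenario_id("HC-HD-wet"))
print(f"HC-HD-wet wetland/estuary area 2050: "
      f"{ds.wetland_estuary_area[-1]:.3f} x baseline "
      f"(+{100 * (ds.wetland_estuary_area[-1] - 1):.1f}%)")
print(f"HC-HD-wet population 2050: {ds.population[-1]:,.0f} "
      f"(from {ds.population[0]:,.0f})")
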