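"""Management sweep: total 2050 biomass under the five regulation levels.

Each level resolves to sanctuary extension, harvest caps (as a fraction
of virgin biomass), bag/size relaxations and human-use mortality caps.
Protection reaches a group in proportion to its site attachment, so
sedentary reef species benefit most.
"""
from marinefutures import (calibrate_dynamics, compute_ecopath_balance,
                           kimberley_fixture, parse_scenario_id,
                           resolve_strategy)
from marinefutures.pipeline import run_cell

web, _, sens = kimberley_fixture()
bw = compute_ecopath_balance(web)
dp = calibrate_dynamics(bw, 1.5)
sc = parse_scenario_id("HC-HD-dry")   # the high-pressure representative

print(f"{'strategy':9s} {'sanctuary':>9s} {'total B(2050)':>14s} "
      f"{'snappers':>9s}")
for level in ("Worst", "Reversed", "Low", "Medium", "High"):
    sp = resolve_strategy(level)
    ts = run_cell(web, bw, dp, sc, level, sens)
    total = ts.end_state[web.living].sum()
    snap = ts.end_state[web.index("snappers")]
    print(f"{level:9s} {sp.sanctuary_fraction_of_parks:9.0%} "
          f"{total:11.1f} t/km^2 {snap:8.2f}")
print("\nTotal biomass rises monotonically with regulation pressure; the "
      "gain concentrates in exploited, site-attached groups.")
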