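# marinefutures

Decadal scenario analysis for marine foodwebs: what happens to a
tropical-shelf ecosystem by 2050 under combinations of climate change,
socio-economic development and management regulation?

The package is aimed at ecosystem modellers and conservation analysts
who want a tested, fully synthetic-input version of the classic
workflow: a mass-balance trophic model is turned into a dynamic
simulation, forced by climate- and development-linked multiplier time
series, run across a scenario grid under alternative management
strategies, and summarised by divergence-based clustering and
winner/loser indicator classification.

## The model

**Static balance.** An ecosystem of functional groups *i* with biomass
density `B_i` (t·km⁻²), production/biomass `PB_i` and consumption/biomass
`QB_i` (yr⁻¹) satisfies, per living group,

```
B_i·PB_i·EE_i = Σ_j B_j·QB_j·DC_ij + catch_i + exports_i
```

where `DC_ij` is the fraction of prey *i* in predator *j*'s diet and
`EE_i ∈ [0,1]` is the ecotrophic efficiency. Balancing yields baseline
flows `Q0_ij` and non-predation mortality `M0_i = PB_i(1 − EE_i)`.

**Dynamics.** Consumption follows the foraging-arena form

```
Q_ij = a_ij·v_ij·B_i·B_j / (2·v_ij + a_ij·B_j)
```

with search rate `a_ij` and vulnerability exchange rate `v_ij`
calibrated so every link reproduces `Q0_ij` exactly at baseline; the
vulnerability multiplier κ ≥ 1 interpolates from donor control (κ→1) to
mass action (κ→∞). Producers grow at a saturating rate
`r·B/(1 + h·B)`; detritus is a passive pool. Biomass ODEs are forced by
per-group annual multipliers on production, consumption, natural
mortality, fishing mortality and vulnerability, and integrated
2015–2050.

**Scenarios.** A 3×3×2 grid: climate level (RCP2.6 / 4.5 / 8.5, with the
RCP4.5 forcing the node-wise mean of the bracketing series),
development level (population and tourism growth 1.5 / 2.0 / 2.5 %/yr,
compounding into recreational fishing and coastal human-use mortality)
and precipitation regime (wet scenarios gain wetland/estuary habitat —
+17.9% by 2050 in the high/high/wet cell — dry scenarios lose it;
wetland-associated groups feed ∝ w(t) and suffer mortality ∝ 1/w(t)).

**Management.** Five regulation levels (High → Worst) resolve to
sanctuary extension (protected fraction p, effective per-group fishing
multiplier `1 − σ_i·p` with σ the site attachment), harvest caps
`F ≤ h·PB`, bag/size relaxations and human-use mortality caps.

**Summary statistics.** Scenario end states are compared by Total
Divergence, the generalized Kullback–Leibler (I-)divergence
`TD(a,b) = Σ_i [a_i·ln(a_i/b_i) − a_i + b_i]`, which also registers
changes in total biomass; scenarios are clustered by average linkage on
the symmetrized divergence, with bootstrap co-assignment support.
Indicators (biomass aggregates) are winners if their 2050/2015 change
ratio is positive in every scenario, losers if negative in every
scenario.

Because real inputs of such studies (calibrated regional trophic
models, land-use simulator output, downscaled ocean projections) are
not redistributable, the package ships a ~25-group tropical-shelf
analogue fixture (`kimberley_fixture()`) and generators for random
balanced webs and terrestrial driver series.

## Worked example

```bash
python examples/04_management_strategies.py
```

prints, for the high-pressure scenario (high climate, high development,
dry):

```
strategy  sanctuary  total B(2050)  snappers
Worst            0%       341.8 t/km^2     1.89
Reversed         0%       341.9 t/km^2     1.95
Low             10%       342.1 t/km^2     2.09
Medium          20%       342.7 t/km^2     2.37
High            30%       345.1 t/km^2     3.64
```

Total 2050 biomass rises monotonically with regulation pressure, and
the gain concentrates in exploited site-attached groups: snappers
(baseline 3.0 t·km⁻²) end almost twice as high under High regulation as
under the Worst case. The other examples cover mass balance
(`01`), equilibrium and forcing (`02`), the scenario grid arithmetic
(`03` — the 68/99/137% compounded mortality totals and the 17.9%
wetland gain) and a reduced end-to-end experiment with clustering and
classification (`05`).

The full experiment (18 scenarios × 5 strategies, reports written as
tidy CSV/JSON) runs from the shell:

```bash
marinefutures run --outdir results/full
```

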