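# Methods

This note documents the model equations, the parameter choices that
matter, what the synthetic inputs do and do not emulate, and the
numerical decisions, in the package's own terms.

## Mass balance

The static description is the standard trophic mass balance: for each
living group, production `B·PB` times ecotrophic efficiency equals the
sum of predation flows `Q0_ij = B_j·QB_j·DC_ij`, catches `F0·B0` and
exports. All biomasses are inputs, so the solve is a direct evaluation
of EE per group (the solve-for-missing-biomass variant is deliberately
out of scope); a group whose EE exceeds 1 raises a balance error naming
it. Detritus is treated as a donor pool: its inflow is the sum of
unassimilated consumption and non-predation deaths, its EE the fraction
of inflow consumed by detritivores, and multiple detritus pools split
the inflow in proportion to baseline biomass.

## Dynamics and calibration

Per-link consumption uses the foraging-arena form
`Q = a·v·B_prey·B_pred / (2v + a·B_pred)`. Given a vulnerability
multiplier κ ≥ 1 per link (the ratio of maximum to baseline predation
flow), the calibration

```
v = κ·Q0/B0_prey ,   a = 2v / (B0_pred·(κ − 1))
```

reproduces `Q0` exactly at baseline, so the unforced system starts at a
fixed point by construction (tests assert < 1% drift over 35 years; the
observed drift is ~1e-8). κ = 1 is the donor-control limit with
infinite search rate; internally κ is floored at 1 + 1e-9 so that
setting 1 gives near-donor control with finite parameters. As κ → ∞ the
flow approaches mass action, `Q → Q0·B_prey·B_pred/(B0_prey·B0_pred)`.

Producers use `r·B/(1 + h·B)` with `h = 1/B0` and `r = 2·PB`: baseline
production matches PB, and the per-capita rate at low biomass is twice
baseline, a moderate compensatory response. Consumers convert
consumption to production at the baseline gross efficiency `g = PB/QB`.
Detritus outflow beyond detritivory is first-order with a rate chosen
to balance at baseline.

Forcing is multiplicative on five channels — producer production rate,
consumer search rates (as predator), non-predation natural mortality,
fishing mortality, and vulnerability (as prey) — defined on 36 annual
nodes (2015–2050, value 1.0 at 2015) and interpolated piecewise
linearly, giving a continuous right-hand side. Multiple forcing sources
(climate, development, terrestrial, management) combine by elementwise
product, except the fishing channel, which is assembled in one pass
(spatial protection and bag relaxation on the commercial/recreational
split, compounding tourism effort, then the harvest cap) to avoid
product-of-multipliers distortion; management phases in over the first
year so the 2015 node keeps its baseline meaning.

Integration uses an adaptive explicit Runge–Kutta method
(scipy `solve_ivp`, RK45, rtol 1e-8, max step 1 year) sampled monthly;
a fixed tiny-step RK4 integrator in the test suite is the independent
oracle (agreement within 1e-3 relative). Biomass is floored at
1e-6·B0: the derivative of a floored, still-declining group is clamped
to zero and the event logged. Everything is deterministic given inputs.

## Scenario forcing

Climate acts per guild as a linear ramp from 1.0 (2015) to an
end-of-horizon multiplier specified under RCP8.5 and RCP2.6; RCP4.5 is
the node-wise arithmetic mean of the two. Guilds flagged as driven by
physical (temperature-linked) anomalies instead scale the RCP8.5
deviation from 1 by the radiative-forcing ratio (4.5/8.5 or 2.6/8.5).
A guild ramp can act on any channel; the prefix `inv:` applies the
reciprocal (used to convert a pressure multiplier into a mortality
increase). The published per-species forcing series behind such studies
are not available, so the shipped end-multipliers are package defaults
(see "Fixture" below) and fully configurable.

Development acts through two paths: recreational fishing mortality
compounds with tourism growth (1.5/2.0/2.5 %/yr by level — over 35
years a 68/99/137 whole-percent increase), and a coastal human-use
mortality increment grows with tourism activity and population relative
to 2015, weighted by site attachment and clipped at the management
strategy's accepted-mortality caps (base rates 0.01 and 0.005 yr⁻¹ at
baseline intensity; invented, configurable). The caps are interpreted
as annual-rate ceilings, not horizon totals.

Terrestrial coupling maps relative wetland/estuary area w(t) onto
wetland-associated groups: feeding ×w, natural mortality and
vulnerability ×1/w. The direction (habitat gain ⇒ lower mortality, more
refuge) is an interpretation; the proportionality itself is the stated
mechanism. Sediment yield is generated and reported but does not force
the web by default, as no marine response rule is defined for it.

Precipitation acts only through the terrestrial drivers: wet scenarios
gain wetlands (endpoint 1 + 0.179·c·d, with c and d level factors of
0.6/0.8/1.0 for climate and development, so high/high/wet ends at
1.179), dry scenarios end at 0.95/0.90/0.85 by development level
(defaults; the dry endpoints are not externally specified). Population
compounds from a 40,000 baseline; pure compounding gives ~80,000 by
2050 at the medium rate, which understates the upper end of the
~60,000–120,000 range such projections quote — the generator documents
rather than fudges this. Tourism activity days are back-computed from
the mid-century targets (7.7/9.8/12.5 M days) and the growth rates.
Driver noise (AR(1), multiplicative) is off by default so experiment
runs are deterministic.

## Management

Spatial protection is collapsed to a scalar protected fraction
p = (park domain fraction, default 0.30 of the model domain) × (sanctuary
fraction of parks per strategy), plus 0.02 for offshore guilds when
Commonwealth reserves are present. A group's fishing multiplier is
`1 − σ·p`: fully sedentary groups (σ = 1) get the whole refuge benefit,
fully mobile ones none. Harvest rules quoted as a percentage h of
virgin biomass are mapped to a cap `F ≤ h·PB` (surplus-production
logic; interpretive). Bag/size relaxations map to recreational-F
multipliers 1.0/1.1/1.25/1.4/1.5 from High to Worst — the regulation
table specifies settings, not catch elasticities, so these are package
defaults. The size-limit direction ("status quo + ~10 cm") is folded
into the same multiplier rather than modelled separately, since the
model has no size structure.

## Indicators and clustering

Total Divergence is the generalized (unnormalized) Kullback–Leibler
divergence `Σ a·ln(a/b) − a + b`: non-negative, zero iff equal,
homogeneous of degree one, and sensitive to total-biomass change
(TD(a, c·a) > 0 for c ≠ 1), unlike composition-only KL. Non-positive
entries are floored at 1e-12 with a log note. The function is pluggable
should a different total-biomass-aware form be preferred. Scenario
distances are the symmetrized divergence; clustering is average-linkage
agglomerative (scipy), cut at k = 3 by default (k is a parameter);
bootstrap support resamples functional-group coordinates with
replacement — the only exchangeable axis an end state offers — and
reports co-assignment fractions over ≥100 replicates under a fixed
seed. Winner/loser classification uses the strict sign of the change
ratio across all scenarios; scenario sensitivity is the range of the
ratio, labelled high above a threshold τ = 0.5 (a config parameter —
any such cut is a presentation choice).

The shipped indicator table defines 14 indicators in five classes
(meta-groups, keystone, charismatic, habitat, system); the system slot
is the Total Divergence of the end state from baseline. A fifteenth
slot is left open deliberately: the enumerated standard list resolves
to fourteen.

## The fixture and what passing tests show

`kimberley_fixture()` ships a hand-built 27-group tropical-shelf web
(4 producers, 22 consumers, detritus) with prawn, barramundi, snapper,
emperor, threadfin, mackerel, shark, dolphin, dugong, turtle, seabird
and habitat-forming groups, plus diet matrix, site attachments, wetland
flags and guild climate sensitivities, versioned as CSVs. Parameter
values are invented within literature-plausible ranges: the fixture is
an analogue of a calibrated 59-group regional model, not a
reconstruction, and the guild end-multipliers were chosen so that the
expected qualitative pattern emerges — seagrass and its grazers
(turtles, dugong) winning, corals, target fish, snubfin dolphin and
pelagic sharks losing, climate dominating development in scenario
distances. The experiment default vulnerability is κ = 1.5 (moderate
top-down coupling); at κ = 2 trophic cascades are strong enough on this
web to (marginally) break the monotone biomass-vs-regulation ordering
and to spread terrestrial coupling effects onto non-wetland groups,
which is a legitimate dynamical regime but not the one the analogue is
meant to represent.

Consequently, passing tests demonstrate that the *rules* are
implemented correctly (balance arithmetic, calibration identities,
forcing construction, divergence and clustering, classification logic)
and that the *pattern-level* findings are reproducible on a plausible
web; they do not validate any quantitative projection for a real
ecosystem, which would require the unpublished calibrated
parameterization and forcing inputs.

## Problem sizes and tolerances

The test suite and the acceptance script run the full 18-scenario
status-quo grid (≈7 s), a 3-scenario × 5-strategy management sweep,
both ablation pairs, 5 generated webs of 12–14 groups, 300 randomized
divergence draws and 100–200-replicate bootstraps — sizes chosen so the
whole suite completes in well under a minute while still exercising
every stage at full grid width. Key tolerances: balance residual 1e-9
(observed ~1e-16), calibration reproduction 1e-6 relative, equilibrium
drift 1% over 35 years (observed ~1e-8), integrator-vs-oracle 1e-3,
divergence-vs-oracle 1e-12.

## Known limitations

No spatial grid (protection is the scalar σ·p model), no age/stanza
structure, no mediation or nutrient-recycling feedbacks, no fitting to
abundance time series, no ocean-acidification channel, linear climate
ramps between 2015 and 2050, and a single-pool passive detritus. The
bag/size elasticities, human-use mortality base rates and dry-scenario
wetland endpoints are invented defaults exposed as configuration.
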