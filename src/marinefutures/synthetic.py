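"""Generators for every input the pipeline needs.

Real decadal studies of this kind rest on inputs that cannot be
redistributed: a calibrated regional trophic model, land-use simulator
output, and downscaled ocean projections. This module generates
structurally equivalent stand-ins: random balanced foodwebs with a
trophic ordering, and terrestrial driver time series (wetland/estuary
extent, population, tourism activity, sediment yield) following the
scenario definitions. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import N_YEARS, YEARS
from .foodweb import (
    BalancedWeb,
    FoodWeb,
    FunctionalGroup,
    compute_ecopath_balance,
)
from .scenarios import TAD_2050, DriverSeries, Scenario

__all__ = [
    "GeneratorConfig",
    "generate_foodweb",
    "generate_terrestrial_drivers",
    "GenerationError",
]

#: Kimberley-region baseline population used by the driver generator
BASE_POPULATION = 40_000.0

#: dry-scenario wetland/estuary endpoints by development level
DRY_WETLAND_END = {"low": 0.95, "medium": 0.90, "high": 0.85}
#: wet-scenario wetland gain scale; the high/high/wet endpoint is
#: 1 + WET_GAIN (a 17.9% gain), lower levels scale the gain down
WET_GAIN = 0.179
_LEVEL_FACTOR = {"low": 0.6, "medium": 0.8, "high": 1.0}


class GenerationError(RuntimeError):
    """Raised when the repair loop cannot balance a generated web."""


@dataclass
class GeneratorConfig:
    """Knobs of the random foodweb generator.

    Webs are trophically ordered: producers at the base, consumers
    feeding strictly downward in rank. The repair loop rescales diets
    until every group's ecotrophic efficiency is at most `ee_target`.
    """

    n_groups: int = 15
    connectance: float = 0.2
    seed: int = 0
    producer_fraction: float = 0.25
    b0_producer: tuple[float, float] = (5.0, 50.0)
    pb_producer: tuple[float, float] = (8.0, 40.0)
    pb_consumer: tuple[float, float] = (0.4, 6.0)
    qb_over_pb: tuple[float, float] = (3.0, 6.0)
    unassim_range: tuple[float, float] = (0.2, 0.4)
    ee_target: float = 0.95
    max_repair_iter: int = 500

    def __post_init__(self):
        if not 0.0 < self.connectance < 1.0:
            raise ValueError("connectance must lie in (0, 1)")
        if self.n_groups < 3:
            raise ValueError("need at least 3 groups")
        for name in ("b0_producer", "pb_producer", "pb_consumer",
                     "qb_over_pb", "unassim_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"{name}: range must be positive and ordered")


def generate_foodweb(cfg: GeneratorConfig) -> FoodWeb:
    """Random trophically-ordered web, repaired until it balances.

    The layout is one detritus pool, ceil(producer_fraction * n) primary
    producers, and consumers ranked above them; each consumer eats a
    random (connectance-controlled) subset of strictly lower-ranked
    groups with Dirichlet diet weights. If any group's EE exceeds the
    target, the offending diet fractions are shifted to detritus and the
    web re-balanced, for at most `max_repair_iter` rounds.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_groups
    n_prod = max(1, int(round(cfg.producer_fraction * (n - 1))))
    n_cons = n - 1 - n_prod
    if n_cons < 1:
        raise ValueError("config leaves no room for consumers")

    groups: list[FunctionalGroup] = []
    groups.append(FunctionalGroup("detritus", "detritus",
                                  B0=float(rng.uniform(50, 200)), PB=0.0,
                                  guild="detritus"))
    for i in range(n_prod):
        groups.append(FunctionalGroup(
            f"producer_{i}", "producer",
            B0=float(rng.uniform(*cfg.b0_producer)),
            PB=float(rng.uniform(*cfg.pb_producer)),
            site_attachment=float(rng.uniform(0.5, 1.0)),
            guild="producer",
        ))
    # consumers: biomass and rates decay with trophic rank
    for i in range(n_cons):
        rank = i + 1
        decay = 0.55 ** rank
        pb = float(rng.uniform(*cfg.pb_consumer)) * max(decay, 0.05)
        qb = pb * float(rng.uniform(*cfg.qb_over_pb))
        groups.append(FunctionalGroup(
            f"consumer_{i}", "consumer",
            B0=float(rng.uniform(1.0, 20.0)) * max(decay, 0.05),
            PB=pb, QB=qb,
            unassim=float(rng.uniform(*cfg.unassim_range)),
            site_attachment=float(rng.uniform(0.0, 1.0)),
            wetland_associated=bool(rng.random() < 0.2),
            guild="consumer",
        ))

    names = [g.name for g in groups]
    det = 0
    diet = np.zeros((n, n))
    first_cons = 1 + n_prod
    for j in range(first_cons, n):
        candidates = list(range(1, j))  # strictly lower-ranked living groups
        k = max(1, int(round(cfg.connectance * len(candidates))))
        k = min(k, len(candidates))
        prey = rng.choice(candidates, size=k, replace=False)
        w = rng.dirichlet(np.ones(k + 1))  # last share goes to detritus
        for p, frac in zip(prey, w[:-1]):
            diet[p, j] = frac
        diet[det, j] = w[-1]

    web = FoodWeb(groups, diet)
    return _repair(web, cfg)


def _repair(web: FoodWeb, cfg: GeneratorConfig) -> FoodWeb:
    det = [i for i, g in enumerate(web.groups) if g.role == "detritus"][0]
    diet = web.diet.copy()
    for _ in range(cfg.max_repair_iter):
        try:
            bw = compute_ecopath_balance(FoodWeb(web.groups, diet))
            over = [i for i, g in enumerate(web.groups)
                    if g.is_living and bw.EE[i] > cfg.ee_target]
            if not over:
                return FoodWeb(web.groups, diet)
        except Exception:
            # EE > 1 raises; find offenders from raw demand instead
            over = _overloaded(web, diet, cfg.ee_target)
            if not over:
                raise
        # shift diet pressure on overloaded prey into the detritus pool
        for i in over:
            excess = diet[i, :] * 0.3
            diet[det, :] += excess
            diet[i, :] -= excess
    raise GenerationError(
        "could not balance the generated web; try a lower connectance"
    )


def _overloaded(web: FoodWeb, diet: np.ndarray, target: float) -> list[int]:
    B0, PB, QB = web.vector("B0"), web.vector("PB"), web.vector("QB")
    F0 = web.vector("F0_commercial") + web.vector("F0_recreational")
    Q0 = diet * (B0 * QB)[np.newaxis, :]
    out = []
    for i, g in enumerate(web.groups):
        if not g.is_living:
            continue
        demand = Q0[i].sum() + F0[i] * B0[i] + web.exports[i]
        if demand > target * B0[i] * PB[i]:
            out.append(i)
    return out


def generate_terrestrial_drivers(
    sc: Scenario,
    seed: int = 0,
    noise_sd: float = 0.0,
    noise_phi: float = 0.6,
) -> DriverSeries:
    """Terrestrial driver series for one scenario, 2015-2050.

    Population and tourism compound at the development level's annual
    rates (tourism back-computed from its mid-century activity-day
    target). Wetland/estuary extent follows a smooth monotone path to a
    2050 endpoint set by climate, development and precipitation: wet
    scenarios gain wetlands (17.9% for high climate / high development),
    dry scenarios lose them. Sediment yield co-varies with precipitation
    and development. Optional AR(1) noise (off by default) perturbs the
    wetland and sediment series multiplicatively.
    """
    t = (YEARS - YEARS[0]).astype(float)
    dev = sc.development
    clim = sc.climate

    population = BASE_POPULATION * (1.0 + dev.pop_growth) ** t
    tad_end = TAD_2050[dev.level]
    tad_base = tad_end / (1.0 + dev.tourism_growth) ** t[-1]
    tourism = tad_base * (1.0 + dev.tourism_growth) ** t

    if clim.precipitation == "wet":
        gain = WET_GAIN * _LEVEL_FACTOR[clim.level] * _LEVEL_FACTOR[dev.level]
        w_end = 1.0 + gain
    else:
        w_end = DRY_WETLAND_END[dev.level]
    x = t / t[-1]
    smooth = 3 * x**2 - 2 * x**3  # smoothstep: monotone, flat at both ends
    wetland = 1.0 + (w_end - 1.0) * smooth

    sed_end = (1.25 if clim.precipitation == "wet" else 0.9)
    sed_end *= 1.0 + 0.1 * ("low", "medium", "high").index(dev.level)
    sediment = 1.0 + (sed_end - 1.0) * smooth

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for series in (wetland, sediment):
            eps = np.zeros(N_YEARS)
            for k in range(1, N_YEARS):
                eps[k] = noise_phi * eps[k - 1] + rng.normal(0.0, noise_sd)
            series *= np.exp(eps - eps[0])

    return DriverSeries(
        scenario_id=sc.id,
        wetland_estuary_area=wetland,
        population=population,
        tourism_activity_days=tourism,
        sediment_yield=sediment,
    )
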