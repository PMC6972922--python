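"""Management strategies: five regulation levels resolved to fishing caps,
spatial protection and human-use mortality caps.

Each strategy is one column of a regulation table spanning a spectrum of
political attitudes to marine conservation, from High (expanded
sanctuaries, 20% harvest of virgin biomass, tight human-use mortality
caps) down to Worst (no parks, no caps). Spatial protection is collapsed
to a scalar protected fraction p of the model domain: a group with site
attachment sigma sees its fishing mortality reduced by the factor
(1 - sigma * p), so sedentary species gain the full refuge benefit and
fully mobile ones none. Harvest rules expressed as a percentage h of
virgin biomass map to a mortality cap F_cap = h * PB (surplus-production
logic). Bag/size relaxations map to recreational-fishing multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import BASE_YEAR, N_YEARS, YEARS
from .foodweb import FoodWeb

__all__ = [
    "StrategyParams",
    "FishingMods",
    "STRATEGY_LEVELS",
    "resolve_strategy",
    "apply_strategy",
    "fishing_channel",
]

#: regulation levels, weakest to strongest
STRATEGY_LEVELS = ("Worst", "Reversed", "Low", "Medium", "High")

# level -> (state parks, commonwealth reserves, sanctuary fraction of parks,
#           harvest fraction prawns, harvest fraction finfish,
#           bag multiplier, size-limit shift cm (None = no limit),
#           tourism mortality cap /yr, other-use mortality cap /yr)
_TABLE = {
    "High":     (True,  True,  0.30, 0.20, 0.20, 1,  0.0,   0.003, 0.003),
    "Medium":   (True,  True,  0.20, 0.50, 0.50, 2,  0.0,   0.01,  0.01),
    "Low":      (True,  False, 0.10, 0.90, 0.70, 5,  10.0,  0.05,  0.05),
    "Reversed": (True,  False, 0.00, 0.90, 0.70, 10, 15.0,  np.inf, np.inf),
    "Worst":    (False, False, 0.00, 0.90, 0.70, 10, None,  np.inf, np.inf),
}

# bag/size relaxation -> recreational-F multiplier (configurable elasticity
# stand-ins; the regulation table gives settings, not catch responses)
REC_F_MULTIPLIER = {
    "High": 1.0, "Medium": 1.1, "Low": 1.25, "Reversed": 1.4, "Worst": 1.5,
}

#: extra protected fraction contributed by Commonwealth reserves, applied
#: to offshore guilds only
COMMONWEALTH_FRACTION = 0.02
OFFSHORE_GUILDS = frozenset({"pelagic_shark", "pelagic_fish", "mackerel"})


@dataclass(frozen=True)
class StrategyParams:
    """One resolved regulation level."""

    level: str
    state_parks_present: bool
    commonwealth_reserves_present: bool
    sanctuary_fraction_of_parks: float
    harvest_fraction_prawns: float
    harvest_fraction_finfish: float
    bag_multiplier: int
    size_limit_shift: float | None  # cm beyond status quo; None = no limit
    tourism_mortality_cap: float
    other_use_mortality_cap: float

    @property
    def rank(self) -> int:
        """Total ordering Worst < Reversed < Low < Medium < High."""
        return STRATEGY_LEVELS.index(self.level)

    @property
    def recreational_multiplier(self) -> float:
        return REC_F_MULTIPLIER[self.level]

    def harvest_fraction(self, stock_class: str) -> float:
        if stock_class == "prawns":
            return self.harvest_fraction_prawns
        return self.harvest_fraction_finfish


def resolve_strategy(level: str) -> StrategyParams:
    """Return the regulation-table row for a named level."""
    if level not in _TABLE:
        raise KeyError(
            f"unknown strategy {level!r}; expected one of {STRATEGY_LEVELS}"
        )
    row = _TABLE[level]
    return StrategyParams(
        level=level,
        state_parks_present=row[0],
        commonwealth_reserves_present=row[1],
        sanctuary_fraction_of_parks=row[2],
        harvest_fraction_prawns=row[3],
        harvest_fraction_finfish=row[4],
        bag_multiplier=row[5],
        size_limit_shift=row[6],
        tourism_mortality_cap=row[7],
        other_use_mortality_cap=row[8],
    )


@dataclass
class FishingMods:
    """Per-group fishing modifications implied by a strategy."""

    web: FoodWeb
    protected_fraction: np.ndarray      # p_i in [0, 1]
    commercial_factor: np.ndarray       # static multiplier on commercial F
    recreational_factor: np.ndarray     # static multiplier on recreational F
    f_cap: np.ndarray                   # F_cap,i = h_class(i) * PB_i (yr^-1)
    tourism_mortality_cap: float
    other_use_mortality_cap: float
    strategy: StrategyParams | None = None

    def effective_f_multiplier(self, tourism_growth: float = 0.0) -> np.ndarray:
        """Combined fishing-mortality channel, shape (n_groups, 36)."""
        return fishing_channel(self.web, self, tourism_growth)


def stock_class(guild: str) -> str:
    """Prawn stocks are capped separately from finfish."""
    return "prawns" if "prawn" in guild else "finfish"


def apply_strategy(
    sp: StrategyParams,
    web: FoodWeb,
    park_domain_fraction: float = 0.30,
) -> FishingMods:
    """Resolve a strategy into per-group fishing modifications.

    The protected fraction is p = park_domain_fraction * sanctuary
    fraction (zero without state parks), plus a small Commonwealth
    reserve fraction for offshore guilds; the per-group fishing
    multiplier is (1 - sigma_i * p_i) with bag/size relaxation applied
    to the recreational component, and realized F is capped at
    h_class * PB.
    """
    if not 0.0 <= park_domain_fraction <= 1.0:
        raise ValueError("park_domain_fraction must lie in [0, 1]")
    n = web.n
    sigma = web.vector("site_attachment")
    PB = web.vector("PB")

    p_state = (park_domain_fraction * sp.sanctuary_fraction_of_parks
               if sp.state_parks_present else 0.0)
    p = np.full(n, p_state)
    if sp.commonwealth_reserves_present:
        for i, g in enumerate(web.groups):
            if g.guild in OFFSHORE_GUILDS:
                p[i] += COMMONWEALTH_FRACTION
    p = np.clip(p, 0.0, 1.0)

    spatial = 1.0 - sigma * p
    f_cap = np.array([
        sp.harvest_fraction(stock_class(g.guild)) * PB[i] if g.is_living else np.inf
        for i, g in enumerate(web.groups)
    ])
    return FishingMods(
        web=web,
        protected_fraction=p,
        commercial_factor=spatial.copy(),
        recreational_factor=spatial * sp.recreational_multiplier,
        f_cap=f_cap,
        tourism_mortality_cap=sp.tourism_mortality_cap,
        other_use_mortality_cap=sp.other_use_mortality_cap,
        strategy=sp,
    )


def fishing_channel(
    web: FoodWeb, mods: FishingMods, tourism_growth: float
) -> np.ndarray:
    """Assemble the fishing-mortality channel (n_groups x 36).

    Combines spatial protection, bag/size relaxation and compounding
    recreational effort into a single per-group multiplier series on
    total baseline F, then clips so realized F never exceeds F_cap.
    Groups with no baseline fishing keep multiplier 1. Regulation phases
    in over the first year, so the 2015 node stays at the baseline value
    of 1.0.
    """
    t = YEARS - BASE_YEAR
    growth = (1.0 + tourism_growth) ** t
    Fc = web.vector("F0_commercial")
    Fr = web.vector("F0_recreational")
    F0 = Fc + Fr
    m = np.ones((web.n, N_YEARS))
    for i in range(web.n):
        if F0[i] <= 0:
            continue
        series = (Fc[i] * mods.commercial_factor[i]
                  + Fr[i] * mods.recreational_factor[i] * growth) / F0[i]
        series = np.minimum(series, mods.f_cap[i] / F0[i])
        series[0] = 1.0
        m[i, :] = series
    return m
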