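"""Scenario grid and forcing-function construction.

The future is explored on a 3 x 3 x 2 grid: three climate-change levels
(tied to RCP2.6 / RCP4.5 / RCP8.5), three socio-economic development
levels (population and tourism growth of 1.5 / 2.0 / 2.5 % per year),
and two precipitation regimes (dry / wet), giving 18 scenarios over
2015-2050.

Climate forcing is expressed as per-guild biomass-forcing ramps: each
guild ramps linearly from 1.0 in 2015 to its end-of-horizon multiplier,
specified under RCP8.5 and RCP2.6. The medium level (RCP4.5) is the
node-by-node arithmetic mean of the two bracketing series; guilds driven
by physical (temperature-linked) anomalies instead scale the RCP8.5
deviation from baseline by the radiative-forcing ratio (4.5/8.5 or
2.6/8.5).

Development forcing compounds tourism growth into recreational fishing
mortality and population growth into a coastal human-use mortality
increment. Terrestrial coupling maps relative wetland/estuary area w(t)
onto wetland-associated groups: feeding rates scale with w, natural
mortality and vulnerability to predation with 1/w (habitat gain means
more food and more refuge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import BASE_YEAR, N_YEARS, YEARS, ForcingSeries
from .foodweb import FoodWeb

__all__ = [
    "ClimateScenario",
    "DevelopmentScenario",
    "Scenario",
    "DriverSeries",
    "GuildResponse",
    "GuildSensitivity",
    "enumerate_scenarios",
    "parse_scenario_id",
    "compound_increase",
    "whole_percent",
    "build_climate_forcing",
    "build_development_forcing",
    "couple_terrestrial",
]

LEVELS = ("low", "medium", "high")
PRECIP = ("dry", "wet")

# level -> (RCP label, radiative forcing W m^-2, mid-century warming degC,
#           mid-century sea-level rise m)
RCP_TABLE = {
    "low": ("RCP2.6", 2.6, 1.0, 0.24),
    "medium": ("RCP4.5", 4.5, 1.4, 0.26),
    "high": ("RCP8.5", 8.5, 2.0, 0.30),
}

# level -> (population growth /yr, tourism growth /yr, cropland 1000 ha,
#           cattle heads, oil & gas label)
DEV_TABLE = {
    "low": (0.015, 0.015, 40.0, 600_000, "as_current"),
    "medium": (0.020, 0.020, 60.0, 1_100_000, "blina_ungani_400k_browse_7.5"),
    "high": (0.025, 0.025, 100.0, 1_240_000, "blina_ungani_600k_browse_10"),
}

#: mid-century tourism activity-day targets per development level
TAD_2050 = {"low": 7.7e6, "medium": 9.8e6, "high": 12.5e6}

_CLIM_CODE = {"low": "LC", "medium": "MC", "high": "HC"}
_DEV_CODE = {"low": "LD", "medium": "MD", "high": "HD"}
_CODE_CLIM = {v: k for k, v in _CLIM_CODE.items()}
_CODE_DEV = {v: k for k, v in _DEV_CODE.items()}


@dataclass(frozen=True)
class ClimateScenario:
    level: str
    precipitation: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown climate level {self.level!r}")
        if self.precipitation not in PRECIP:
            raise ValueError(f"unknown precipitation regime {self.precipitation!r}")

    @property
    def rcp_label(self) -> str:
        return RCP_TABLE[self.level][0]

    @property
    def radiative_forcing(self) -> float:
        return RCP_TABLE[self.level][1]

    @property
    def warming_midcentury(self) -> float:
        return RCP_TABLE[self.level][2]

    @property
    def slr_midcentury(self) -> float:
        return RCP_TABLE[self.level][3]


@dataclass(frozen=True)
class DevelopmentScenario:
    level: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown development level {self.level!r}")

    @property
    def pop_growth(self) -> float:
        return DEV_TABLE[self.level][0]

    @property
    def tourism_growth(self) -> float:
        return DEV_TABLE[self.level][1]

    @property
    def cropland_target(self) -> float:
        return DEV_TABLE[self.level][2]

    @property
    def cattle_target(self) -> float:
        return DEV_TABLE[self.level][3]

    @property
    def oil_gas_intensity(self) -> str:
        return DEV_TABLE[self.level][4]


@dataclass(frozen=True)
class Scenario:
    """One cell of the 3 (climate) x 3 (development) x 2 (precipitation) grid."""

    climate: ClimateScenario
    development: DevelopmentScenario

    @property
    def id(self) -> str:
        return (f"{_CLIM_CODE[self.climate.level]}-"
                f"{_DEV_CODE[self.development.level]}-"
                f"{self.climate.precipitation}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Scenario {self.id}>"


def enumerate_scenarios() -> list[Scenario]:
    """The full 18-scenario grid in stable (climate, development,
    precipitation) nesting order."""
    out = []
    for clim in LEVELS:
        for dev in LEVELS:
            for pr in PRECIP:
                out.append(Scenario(ClimateScenario(clim, pr),
                                    DevelopmentScenario(dev)))
    return out


def parse_scenario_id(sid: str) -> Scenario:
    """Inverse of Scenario.id (e.g. 'HC-HD-dry')."""
    try:
        c, d, p = sid.split("-")
        return Scenario(ClimateScenario(_CODE_CLIM[c], p),
                        DevelopmentScenario(_CODE_DEV[d]))
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed scenario id {sid!r}") from exc


def compound_increase(rate: float, years: int) -> float:
    """Percent increase from `years` of compounding at annual `rate`.

    100 * ((1 + rate)**years - 1); e.g. 1.5 %/yr over 35 years -> 68.39.
    """
    if rate <= -1:
        raise ValueError("rate must exceed -1")
    if years < 0:
        raise ValueError("years must be >= 0")
    return 100.0 * ((1.0 + rate) ** years - 1.0)


def whole_percent(pct: float) -> int:
    """Truncate to whole percent (the convention used when quoting
    compounded totals)."""
    return int(pct)


@dataclass
class DriverSeries:
    """Annual terrestrial driver series for one scenario, 2015-2050.

    wetland_estuary_area and sediment_yield are relative to 2015 (=1.0);
    population is in persons, tourism_activity_days in days/yr.
    """

    scenario_id: str
    wetland_estuary_area: np.ndarray
    population: np.ndarray
    tourism_activity_days: np.ndarray
    sediment_yield: np.ndarray
    years: np.ndarray = field(default_factory=lambda: YEARS.copy())

    def __post_init__(self):
        for name in ("wetland_estuary_area", "population",
                     "tourism_activity_days", "sediment_yield"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_YEARS,):
                raise ValueError(f"{name}: expected {N_YEARS} annual values")
            if (arr <= 0).any():
                raise ValueError(f"{name}: values must be positive")
            setattr(self, name, arr)


@dataclass
class GuildResponse:
    """Climate response of one guild.

    end_rcp85 / end_rcp26 are the 2050 biomass-forcing multipliers under
    the bracketing RCPs (1.0 = no effect); `channels` names the forcing
    channels the ramp acts on — a channel prefixed ``inv:`` receives the
    reciprocal series (so a pressure multiplier below 1 raises
    mortality); `physical` selects radiative-ratio anomaly scaling for
    the intermediate levels instead of the mean rule.
    """

    end_rcp85: float
    end_rcp26: float
    channels: tuple[str, ...] = ("production",)
    physical: bool = False

    def __post_init__(self):
        if self.end_rcp85 <= 0 or self.end_rcp26 <= 0:
            raise ValueError("end multipliers must be positive")
        if abs(self.end_rcp26 - 1.0) > abs(self.end_rcp85 - 1.0) + 1e-12:
            raise ValueError(
                "RCP2.6 multiplier must be closer to 1 than the RCP8.5 one"
            )


class GuildSensitivity:
    """Mapping guild -> GuildResponse, with config-style construction."""

    def __init__(self, responses: dict[str, GuildResponse]):
        self.responses = dict(responses)

    def __contains__(self, guild: str) -> bool:
        return guild in self.responses

    def __getitem__(self, guild: str) -> GuildResponse:
        return self.responses[guild]

    @classmethod
    def from_dict(cls, d: dict) -> "GuildSensitivity":
        """Build from plain config data, e.g. parsed YAML:
        {guild: {end_rcp85: .., end_rcp26: .., channels: [..], physical: ..}}
        """
        resp = {}
        for guild, spec in d.items():
            resp[guild] = GuildResponse(
                end_rcp85=float(spec["end_rcp85"]),
                end_rcp26=float(spec["end_rcp26"]),
                channels=tuple(spec.get("channels", ("production",))),
                physical=bool(spec.get("physical", False)),
            )
        return cls(resp)


def _ramp(end: float) -> np.ndarray:
    """Linear ramp 1.0 (2015) -> end (2050) on the annual nodes."""
    return np.linspace(1.0, end, N_YEARS)


def climate_multiplier_series(resp: GuildResponse, level: str) -> np.ndarray:
    """Annual multiplier series for one guild at one climate level."""
    s85 = _ramp(resp.end_rcp85)
    s26 = _ramp(resp.end_rcp26)
    if resp.physical:
        # scale the RCP8.5 anomaly by the radiative-forcing ratio
        ratio = RCP_TABLE[level][1] / RCP_TABLE["high"][1]
        return 1.0 + ratio * (s85 - 1.0)
    if level == "high":
        return s85
    if level == "low":
        return s26
    return 0.5 * (s26 + s85)


def build_climate_forcing(
    sc: Scenario, gs: GuildSensitivity, web: FoodWeb
) -> ForcingSeries:
    """Translate per-guild climate responses into a ForcingSeries.

    Every group whose guild appears in `gs` receives that guild's ramp on
    the guild's channels; a guild present in the web but missing from
    `gs` is a configuration error (pass an explicit neutral response to
    silence it).
    """
    missing = sorted({g.guild for g in web.groups
                      if g.is_living and g.guild and g.guild not in gs})
    if missing:
        raise KeyError(f"no climate sensitivity configured for guilds: {missing}")
    forcing = ForcingSeries.identity(web.n)
    for i, grp in enumerate(web.groups):
        if not grp.is_living or not grp.guild:
            continue
        resp = gs[grp.guild]
        series = climate_multiplier_series(resp, sc.climate.level)
        for ch in resp.channels:
            if ch.startswith("inv:"):
                forcing.channels[ch[4:]][i, :] *= 1.0 / series
            else:
                forcing.channels[ch][i, :] *= series
    forcing.validate()
    return forcing


def build_development_forcing(
    sc: Scenario,
    drivers: DriverSeries,
    web: FoodWeb,
    M0: np.ndarray,
    tourism_mortality_base: float = 0.01,
    other_use_mortality_base: float = 0.005,
    tourism_mortality_cap: float = np.inf,
    other_use_mortality_cap: float = np.inf,
) -> ForcingSeries:
    """Development pressure as fishing- and natural-mortality forcing.

    Recreational fishing mortality compounds with tourism growth:
    the F-channel multiplier at year k is
    (F0_comm + F0_rec * (1+g)^(k-2015)) / (F0_comm + F0_rec).

    Coastal human-use mortality grows with tourism activity (capped at
    the strategy's accepted tourism-induced mortality) and population
    (capped at the other-uses mortality), weighted by site attachment;
    it enters the natural-mortality channel as an increment over M0.
    """
    g_tour = sc.development.tourism_growth
    t = YEARS - BASE_YEAR
    rec_growth = (1.0 + g_tour) ** t

    forcing = ForcingSeries.identity(web.n)
    Fc = web.vector("F0_commercial")
    Fr = web.vector("F0_recreational")
    sigma = web.vector("site_attachment")

    tad_rel = drivers.tourism_activity_days / drivers.tourism_activity_days[0]
    pop_rel = drivers.population / drivers.population[0]
    dm_tour = np.minimum(tourism_mortality_base * (tad_rel - 1.0),
                         tourism_mortality_cap)
    dm_other = np.minimum(other_use_mortality_base * (pop_rel - 1.0),
                          other_use_mortality_cap)
    dm = np.maximum(dm_tour, 0.0) + np.maximum(dm_other, 0.0)

    for i, grp in enumerate(web.groups):
        if not grp.is_living:
            continue
        F0 = Fc[i] + Fr[i]
        if F0 > 0:
            forcing.channels["fishing_mortality"][i, :] = (
                (Fc[i] + Fr[i] * rec_growth) / F0
            )
        if M0[i] > 0 and sigma[i] > 0:
            forcing.channels["natural_mortality"][i, :] = (
                1.0 + sigma[i] * dm / M0[i]
            )
    forcing.validate()
    return forcing


def couple_terrestrial(drivers: DriverSeries, web: FoodWeb) -> ForcingSeries:
    """Wetland/estuary coupling for wetland-associated groups.

    With w(t) the relative wetland/estuary area: feeding (consumption)
    multiplier = w(t); natural-mortality and vulnerability multipliers =
    1/w(t). Habitat gain means more food and more refuge from predation;
    non-associated groups are unaffected.
    """
    w = drivers.wetland_estuary_area
    if (w <= 0).any():
        raise ValueError("wetland/estuary area series must be positive")
    forcing = ForcingSeries.identity(web.n)
    idx = [i for i, g in enumerate(web.groups) if g.wetland_associated]
    for i in idx:
        forcing.channels["consumption"][i, :] = w
        forcing.channels["natural_mortality"][i, :] = 1.0 / w
        forcing.channels["vulnerability"][i, :] = 1.0 / w
    forcing.validate()
    return forcing
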