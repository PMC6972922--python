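"""Dynamic biomass simulation under time-varying forcing.

Consumption follows the foraging-arena formulation: prey exchange between
vulnerable and invulnerable pools at rate v_ij, and predators remove
vulnerable prey at search rate a_ij, giving the per-link flow

    Q_ij = a_ij * v_ij * B_i * B_j / (2 * v_ij + a_ij * B_j)

which interpolates between donor control (kappa -> 1) and mass action
(kappa -> inf), where kappa_ij >= 1 is the vulnerability multiplier: the
maximum predation flow on a link is kappa times its baseline flow. Both
link parameters are calibrated so that every link reproduces its
mass-balance baseline flow Q0_ij exactly at B = B0:

    v_ij = kappa_ij * Q0_ij / B0_i        (exchange rate)
    a_ij = 2 * v_ij / (B0_j * (kappa_ij - 1))   (search rate)

Producers grow with a saturating rate r_i * B_i / (1 + h_i * B_i) with
h_i = 1/B0_i and r_i = 2 * PB_i, so baseline production matches PB at B0
and the maximum per-capita rate is twice baseline. Detritus is a passive
pool fed by unassimilated consumption and non-predation deaths, drained
by detritivory and a first-order outflow calibrated to balance.

External forcing enters as per-group annual multiplier series (baseline
1.0) on five channels: producer production rate, consumer search rates
(as predator), non-predation natural mortality, fishing mortality, and
vulnerability (as prey); multipliers are interpolated piecewise-linearly
between annual nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .foodweb import BalancedWeb, FoodWeb

__all__ = [
    "ForcingSeries",
    "DynamicParams",
    "TrajectorySet",
    "calibrate_dynamics",
    "simulate",
    "IntegrationError",
    "YEARS",
    "BASE_YEAR",
    "END_YEAR",
    "N_YEARS",
]

logger = logging.getLogger(__name__)

BASE_YEAR = 2015
END_YEAR = 2050
#: annual forcing nodes, 2015..2050 inclusive
YEARS = np.arange(BASE_YEAR, END_YEAR + 1)
N_YEARS = len(YEARS)  # 36 nodes, 35 elapsed years

CHANNELS = (
    "production",
    "consumption",
    "natural_mortality",
    "fishing_mortality",
    "vulnerability",
)

#: relative biomass floor (fraction of B0)
FLOOR_FRAC = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, msg: str, last_valid_time: float | None = None):
        super().__init__(msg)
        self.last_valid_time = last_valid_time


class ForcingSeries:
    """Per-group, per-channel annual multiplier series over 2015-2050.

    Stored as a mapping channel -> array of shape (n_groups, 36) with
    baseline value 1.0; all multipliers must be positive and equal 1.0
    at the 2015 node.
    """

    def __init__(self, n_groups: int, channels: dict[str, np.ndarray] | None = None):
        self.n_groups = n_groups
        self.channels: dict[str, np.ndarray] = {}
        for ch in CHANNELS:
            arr = None if channels is None else channels.get(ch)
            if arr is None:
                arr = np.ones((n_groups, N_YEARS))
            else:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n_groups, N_YEARS):
                    raise ValueError(
                        f"channel {ch}: expected shape {(n_groups, N_YEARS)}, "
                        f"got {arr.shape}"
                    )
            self.channels[ch] = arr
        self.validate()

    def validate(self) -> None:
        for ch, arr in self.channels.items():
            if (arr <= 0).any():
                raise ValueError(f"channel {ch}: multipliers must be positive")
            if not np.allclose(arr[:, 0], 1.0, atol=1e-12):
                raise ValueError(f"channel {ch}: value at {BASE_YEAR} must be 1.0")

    @classmethod
    def identity(cls, n_groups: int) -> "ForcingSeries":
        return cls(n_groups)

    def copy(self) -> "ForcingSeries":
        return ForcingSeries(
            self.n_groups, {ch: a.copy() for ch, a in self.channels.items()}
        )

    def combine(self, other: "ForcingSeries") -> "ForcingSeries":
        """Elementwise product of two forcing series (stacked drivers)."""
        if other.n_groups != self.n_groups:
            raise ValueError("cannot combine forcings for different webs")
        return ForcingSeries(
            self.n_groups,
            {ch: self.channels[ch] * other.channels[ch] for ch in CHANNELS},
        )

    def set_channel(
        self, channel: str, group_idx: np.ndarray | list[int], series: np.ndarray
    ) -> None:
        """Overwrite the series of `channel` for the given groups."""
        if channel not in CHANNELS:
            raise KeyError(f"unknown forcing channel {channel!r}")
        self.channels[channel][group_idx, :] = series

    def at(self, t: float) -> dict[str, np.ndarray]:
        """Multipliers at elapsed time t (years since 2015), linear interp."""
        x = np.clip(t, 0.0, N_YEARS - 1.0)
        k = min(int(x), N_YEARS - 2)
        f = x - k
        return {
            ch: arr[:, k] * (1.0 - f) + arr[:, k + 1] * f
            for ch, arr in self.channels.items()
        }


@dataclass
class DynamicParams:
    """Calibrated rate constants for the dynamic model.

    All link arrays are parallel: entry l describes the flow of prey
    ``prey_idx[l]`` into predator ``pred_idx[l]``.
    """

    web: FoodWeb
    prey_idx: np.ndarray
    pred_idx: np.ndarray
    a: np.ndarray          # search rates (km^2 t^-1 yr^-1 scale)
    v: np.ndarray          # vulnerability exchange rates (yr^-1 scale)
    kappa: np.ndarray      # vulnerability multipliers per link
    g: np.ndarray          # per-group growth conversion (P/Q), 0 for non-consumers
    r: np.ndarray          # producer max per-capita production (yr^-1)
    h: np.ndarray          # producer saturation constants (km^2 t^-1)
    M0: np.ndarray         # non-predation natural mortality (yr^-1)
    F0: np.ndarray         # baseline total fishing mortality (yr^-1)
    export_rate: np.ndarray  # exports_i / B0_i (yr^-1)
    det_outflow: np.ndarray  # first-order detritus outflow rates (yr^-1)
    B0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def consumption_at(
        self, B: np.ndarray, m_cons: np.ndarray | None = None,
        m_vul: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-link instantaneous consumption flows at state B."""
        a = self.a * (1.0 if m_cons is None else m_cons[self.pred_idx])
        v = self.v * (1.0 if m_vul is None else m_vul[self.prey_idx])
        Bi = B[self.prey_idx]
        Bj = B[self.pred_idx]
        return a * v * Bi * Bj / (2.0 * v + a * Bj)


@dataclass
class TrajectorySet:
    """Simulated biomass and catch trajectories on the monthly grid."""

    web: FoodWeb
    times: np.ndarray          # calendar years (float), monthly spacing
    biomass: np.ndarray        # (n_groups, n_times), t km^-2
    catch: np.ndarray          # (n_groups, n_times), t km^-2 yr^-1
    scenario_id: str = ""
    strategy_id: str = ""
    seed: int | None = None
    floored_groups: list[str] = field(default_factory=list)

    def at_year(self, year: float) -> np.ndarray:
        """Biomass vector at (the grid point nearest to) a calendar year."""
        k = int(np.argmin(np.abs(self.times - year)))
        return self.biomass[:, k]

    @property
    def end_state(self) -> np.ndarray:
        return self.biomass[:, -1]

    def change_ratio(self) -> np.ndarray:
        """Per-group B(end)/B(start) - 1."""
        return self.biomass[:, -1] / self.biomass[:, 0] - 1.0

    def to_frame(self, annual: bool = True) -> pd.DataFrame:
        """Tidy long format: scenario, strategy, group, year, biomass, catch."""
        if annual:
            cols = [int(np.argmin(np.abs(self.times - y))) for y in YEARS]
        else:
            cols = list(range(len(self.times)))
        rows = []
        for i, name in enumerate(self.web.names):
            for k in cols:
                rows.append({
                    "scenario": self.scenario_id,
                    "strategy": self.strategy_id,
                    "group": name,
                    "year": round(float(self.times[k]), 4),
                    "biomass": self.biomass[i, k],
                    "catch": self.catch[i, k],
                })
        return pd.DataFrame(rows)


def calibrate_dynamics(
    bw: BalancedWeb,
    vulnerability: float | dict[tuple[str, str], float] | np.ndarray = 2.0,
) -> DynamicParams:
    """Choose rate constants reproducing the baseline flows at B0.

    Parameters
    ----------
    bw : BalancedWeb
    vulnerability : float, dict or (n, n) array
        Vulnerability multiplier kappa per trophic link (>= 1). A scalar
        applies to every link; a dict maps (prey, predator) name pairs,
        missing links defaulting to 2.

    Returns
    -------
    DynamicParams
        At B = B0 with all forcing at 1, every link's consumption equals
        its baseline flow Q0_ij and dB/dt = 0 for every group.
    """
    web = bw.web
    n = web.n
    B0 = web.vector("B0")
    PB = web.vector("PB")
    QB = web.vector("QB")

    prey, pred = np.nonzero(bw.Q0 > 0)
    kap = np.full(len(prey), 2.0)
    if np.isscalar(vulnerability):
        kap[:] = float(vulnerability)
    elif isinstance(vulnerability, dict):
        for l, (i, j) in enumerate(zip(prey, pred)):
            key = (web.names[i], web.names[j])
            if key in vulnerability:
                kap[l] = float(vulnerability[key])
    else:
        arr = np.asarray(vulnerability, dtype=float)
        kap = arr[prey, pred]
    if (kap < 1.0).any():
        bad = [(web.names[i], web.names[j])
               for l, (i, j) in enumerate(zip(prey, pred)) if kap[l] < 1.0]
        raise ValueError(f"vulnerability multipliers must be >= 1; bad links: {bad}")

    # kappa = 1 is the donor-control limit (infinite search rate); bound it
    # away from 1 so parameters stay finite.
    kap_eff = np.maximum(kap, 1.0 + 1e-9)
    Q0l = bw.Q0[prey, pred]
    v = kap_eff * Q0l / B0[prey]
    a = 2.0 * v / (B0[pred] * (kap_eff - 1.0))

    g = np.zeros(n)
    r = np.zeros(n)
    h = np.zeros(n)
    for i, grp in enumerate(web.groups):
        if grp.role == "consumer":
            g[i] = PB[i] / QB[i]
        elif grp.role == "producer":
            h[i] = 1.0 / B0[i]
            r[i] = 2.0 * PB[i]

    det_idx = [i for i, grp in enumerate(web.groups) if grp.role == "detritus"]
    det_out = np.zeros(n)
    for k, i in enumerate(det_idx):
        consumed = bw.Q0[i].sum()
        surplus = bw.detritus_inflow[k] - consumed
        det_out[i] = max(surplus, 0.0) / B0[i] if B0[i] > 0 else 0.0

    F0 = web.vector("F0_commercial") + web.vector("F0_recreational")
    export_rate = np.where(B0 > 0, web.exports / np.where(B0 > 0, B0, 1.0), 0.0)

    return DynamicParams(
        web=web, prey_idx=prey, pred_idx=pred, a=a, v=v, kappa=kap,
        g=g, r=r, h=h, M0=bw.M0.copy(), F0=F0, export_rate=export_rate,
        det_outflow=det_out, B0=B0,
    )


def _rhs_factory(dp: DynamicParams, forcing: ForcingSeries):
    web = dp.web
    n = web.n
    unassim = web.vector("unassim")
    is_producer = np.array([g.role == "producer" for g in web.groups])
    is_consumer = np.array([g.role == "consumer" for g in web.groups])
    is_detritus = np.array([g.role == "detritus" for g in web.groups])
    floor = FLOOR_FRAC * np.where(dp.B0 > 0, dp.B0, 1.0)

    def rhs(t: float, B: np.ndarray) -> np.ndarray:
        m = forcing.at(t)
        Bc = np.maximum(B, floor)
        Q = dp.consumption_at(Bc, m["consumption"], m["vulnerability"])
        cons_by_pred = np.bincount(dp.pred_idx, weights=Q, minlength=n)
        loss_by_prey = np.bincount(dp.prey_idx, weights=Q, minlength=n)

        prod = np.zeros(n)
        prod[is_producer] = (
            dp.r[is_producer] * m["production"][is_producer] * Bc[is_producer]
            / (1.0 + dp.h[is_producer] * Bc[is_producer])
        )
        prod[is_consumer] = (
            dp.g[is_consumer] * m["production"][is_consumer]
            * cons_by_pred[is_consumer]
        )

        mort = (dp.M0 * m["natural_mortality"]
                + dp.F0 * m["fishing_mortality"]
                + dp.export_rate) * Bc

        dB = prod - loss_by_prey - mort
        if is_detritus.any():
            det_in = float(
                (unassim * cons_by_pred).sum()
                + (dp.M0 * m["natural_mortality"] * Bc).sum()
            )
            share = Bc[is_detritus] / Bc[is_detritus].sum()
            dB[is_detritus] = (
                det_in * share
                - loss_by_prey[is_detritus]
                - dp.det_outflow[is_detritus] * Bc[is_detritus]
            )
        # hold groups pinned at the floor rather than letting them go negative
        dB = np.where((B <= floor) & (dB < 0.0), 0.0, dB)
        return dB

    return rhs, floor


def simulate(
    dp: DynamicParams,
    forcing: ForcingSeries | None = None,
    horizon: tuple[int, int] = (BASE_YEAR, END_YEAR),
    step_months: int = 1,
    rtol: float = 1e-8,
    atol_frac: float = 1e-10,
    scenario_id: str = "",
    strategy_id: str = "",
) -> TrajectorySet:
    """Integrate the forced foodweb ODE over the horizon.

    Uses an adaptive Runge-Kutta integrator sampled on a regular
    (default monthly) grid; biomass is floored at 1e-6 * B0 with a
    logged warning naming the floored groups. Deterministic given
    inputs.
    """
    n = dp.web.n
    if forcing is None:
        forcing = ForcingSeries.identity(n)
    if forcing.n_groups != n:
        raise ValueError("forcing built for a different web")
    y0, y1 = horizon
    if y0 < BASE_YEAR or y1 > END_YEAR or y1 <= y0:
        raise ValueError(f"horizon must lie within {BASE_YEAR}-{END_YEAR}")

    rhs, floor = _rhs_factory(dp, forcing)
    t0, t1 = float(y0 - BASE_YEAR), float(y1 - BASE_YEAR)
    t_eval = np.arange(t0, t1 + 1e-9, step_months / 12.0)

    sol = solve_ivp(
        rhs, (t0, t1), dp.B0.astype(float), t_eval=t_eval,
        method="RK45", rtol=rtol, atol=atol_frac * np.maximum(dp.B0, 1.0).max(),
        max_step=1.0,
    )
    if not sol.success or not np.isfinite(sol.y).all():
        last = sol.t[-1] + BASE_YEAR if len(sol.t) else None
        raise IntegrationError(
            f"integration failed ({sol.message}); last valid year {last}",
            last_valid_time=last,
        )

    Bio = sol.y
    floored = []
    for i in range(n):
        if (Bio[i] < floor[i]).any():
            floored.append(dp.web.names[i])
    if floored:
        logger.warning("biomass floored at 1e-6*B0 for groups: %s", floored)
    Bio = np.maximum(Bio, floor[:, None])

    mF = np.stack([forcing.at(t)["fishing_mortality"] for t in sol.t], axis=1)
    catch = dp.F0[:, None] * mF * Bio

    return TrajectorySet(
        web=dp.web, times=sol.t + BASE_YEAR, biomass=Bio, catch=catch,
        scenario_id=scenario_id, strategy_id=strategy_id,
        floored_groups=floored,
    )
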