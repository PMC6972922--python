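"""Static mass-balance accounting for a marine foodweb.

The ecosystem is described by functional groups (species or aggregates of
ecologically similar species) linked by a diet-composition matrix. The
mass-balance condition per living group i reads

    B_i * PB_i * EE_i = sum_j B_j * QB_j * DC_ij + catch_i + exports_i

where EE_i (ecotrophic efficiency) is the fraction of production consumed
by predation, fishing or export, and must lie in [0, 1] for a balanced
web. Balancing yields the baseline consumption flows Q0_ij and the
non-predation natural mortality M0_i = PB_i * (1 - EE_i) - F0_i used to
initialise the dynamic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "FoodWeb",
    "BalancedWeb",
    "BalanceError",
    "DegenerateInputError",
    "compute_ecopath_balance",
    "read_foodweb",
    "write_foodweb",
]

ROLES = ("producer", "consumer", "detritus")

#: tolerance on diet-column normalisation
DIET_TOL = 1e-9
#: slack allowed on EE before a balance violation is raised
EE_TOL = 1e-9


class BalanceError(ValueError):
    """Raised when predation/catch demands exceed a group's production."""


class DegenerateInputError(ValueError):
    """Raised for structurally impossible webs (e.g. predation on a group
    with zero production)."""


@dataclass
class FunctionalGroup:
    """One compartment of the foodweb.

    Parameters
    ----------
    name : str
        Group label, unique within the web.
    role : {"producer", "consumer", "detritus"}
    B0 : float
        Baseline biomass density (t km^-2).
    PB : float
        Production/biomass ratio (yr^-1); 0 for detritus.
    QB : float
        Consumption/biomass ratio (yr^-1); consumers only, else 0.
    unassim : float
        Unassimilated fraction of consumption, in [0, 1).
    F0_commercial, F0_recreational : float
        Baseline fishing mortality components (yr^-1).
    site_attachment : float
        sigma in [0, 1]; 1 means fully sedentary (full benefit from
        spatial protection), 0 fully mobile.
    wetland_associated : bool
        Whether the group is coupled to wetland/estuary extent.
    guild : str
        Label used to assign climate sensitivities (e.g. "coral",
        "seagrass", "reef_fish", "pelagic_shark").
    """

    name: str
    role: str
    B0: float
    PB: float = 0.0
    QB: float = 0.0
    unassim: float = 0.0
    F0_commercial: float = 0.0
    F0_recreational: float = 0.0
    site_attachment: float = 0.0
    wetland_associated: bool = False
    guild: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for group {self.name!r}")
        if self.role != "detritus" and self.B0 <= 0:
            raise ValueError(f"{self.name}: B0 must be > 0 for living groups")
        if self.role != "detritus" and self.PB <= 0:
            raise ValueError(f"{self.name}: PB must be > 0 for living groups")
        if self.role == "consumer" and self.QB <= self.PB:
            raise ValueError(f"{self.name}: QB must exceed PB for consumers")
        if not 0.0 <= self.unassim < 1.0:
            raise ValueError(f"{self.name}: unassim must lie in [0, 1)")
        if not 0.0 <= self.site_attachment <= 1.0:
            raise ValueError(f"{self.name}: site_attachment must lie in [0, 1]")
        if min(self.F0_commercial, self.F0_recreational) < 0:
            raise ValueError(f"{self.name}: fishing mortalities must be >= 0")

    @property
    def F0(self) -> float:
        """Total baseline fishing mortality (yr^-1)."""
        return self.F0_commercial + self.F0_recreational

    @property
    def is_living(self) -> bool:
        return self.role != "detritus"


class FoodWeb:
    """An ordered collection of functional groups plus the diet matrix.

    ``diet[i, j]`` is the fraction of prey i in the diet of predator j;
    each consumer's column sums to one. ``exports`` are per-group net
    export terms (t km^-2 yr^-1) beyond catches, default zero.
    """

    def __init__(
        self,
        groups: Sequence[FunctionalGroup],
        diet: np.ndarray,
        exports: np.ndarray | None = None,
    ) -> None:
        self.groups = list(groups)
        n = len(self.groups)
        names = [g.name for g in self.groups]
        if len(set(names)) != n:
            raise ValueError("group names must be unique")
        diet = np.asarray(diet, dtype=float)
        if diet.shape != (n, n):
            raise ValueError(f"diet matrix must be {n}x{n}, got {diet.shape}")
        if (diet < 0).any():
            raise ValueError("diet fractions must be >= 0")
        if np.diagonal(diet).any():
            raise ValueError("self-predation (DC_ii != 0) is not allowed")
        for j, g in enumerate(self.groups):
            s = diet[:, j].sum()
            if g.role == "consumer":
                if abs(s - 1.0) > DIET_TOL:
                    raise ValueError(
                        f"diet column of {g.name!r} sums to {s:.12f}, expected 1"
                    )
            elif s > DIET_TOL:
                raise ValueError(f"non-consumer {g.name!r} has a nonzero diet")
        self.diet = diet
        self.exports = (
            np.zeros(n) if exports is None else np.asarray(exports, dtype=float)
        )
        if self.exports.shape != (n,):
            raise ValueError("exports must be a per-group vector")
        self._index = {name: i for i, name in enumerate(names)}

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def index(self, name: str) -> int:
        return self._index[name]

    def __getitem__(self, name: str) -> FunctionalGroup:
        return self.groups[self._index[name]]

    def vector(self, attr: str) -> np.ndarray:
        """Per-group vector of a FunctionalGroup attribute."""
        return np.array([getattr(g, attr) for g in self.groups], dtype=float)

    @property
    def living(self) -> np.ndarray:
        return np.array([g.is_living for g in self.groups])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<FoodWeb: {self.n} groups, {int((self.diet > 0).sum())} links>"


@dataclass
class BalancedWeb:
    """A FoodWeb plus the quantities fixed by the mass-balance solve.

    Attributes
    ----------
    web : FoodWeb
    EE : ndarray
        Ecotrophic efficiency per group (detritus: fraction of inflow
        consumed).
    Q0 : ndarray
        Baseline consumption flows, ``Q0[i, j] = B0_j * QB_j * DC_ij``
        (t km^-2 yr^-1), prey i by predator j.
    M0 : ndarray
        Baseline non-predation, non-fishing natural mortality (yr^-1).
    detritus_inflow : ndarray
        Baseline detrital inflow per detritus group (t km^-2 yr^-1).
    """

    web: FoodWeb
    EE: np.ndarray
    Q0: np.ndarray
    M0: np.ndarray
    detritus_inflow: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def residual(self) -> float:
        """Max relative mass-balance residual over living groups."""
        w = self.web
        B0, PB = w.vector("B0"), w.vector("PB")
        F0 = w.vector("F0_commercial") + w.vector("F0_recreational")
        res = 0.0
        for i, g in enumerate(w.groups):
            if not g.is_living:
                continue
            prod = B0[i] * PB[i]
            demand = self.Q0[i].sum() + F0[i] * B0[i] + w.exports[i]
            res = max(res, abs(prod * self.EE[i] - demand) / prod)
        return res


def compute_ecopath_balance(web: FoodWeb) -> BalancedWeb:
    """Solve the static mass balance of a fully parameterised web.

    All biomasses are given, so the solve reduces to direct evaluation of
    EE_i = (sum_j Q0_ij + catch_i + exports_i) / (B0_i * PB_i) for living
    groups. Detritus EE is consumption over detrital inflow.

    Raises
    ------
    BalanceError
        If any living group has EE > 1 (demand exceeds production) or a
        detritus pool is consumed faster than it is replenished.
    DegenerateInputError
        If a group with zero production is predated or fished.
    """
    n = web.n
    B0 = web.vector("B0")
    PB = web.vector("PB")
    QB = web.vector("QB")
    F0 = web.vector("F0_commercial") + web.vector("F0_recreational")
    unassim = web.vector("unassim")

    # Q0[i, j]: flow of prey i into predator j
    Q0 = web.diet * (B0 * QB)[np.newaxis, :]

    EE = np.zeros(n)
    M0 = np.zeros(n)
    bad: list[str] = []
    for i, g in enumerate(web.groups):
        if not g.is_living:
            continue
        demand = Q0[i].sum() + F0[i] * B0[i] + web.exports[i]
        prod = B0[i] * PB[i]
        if prod <= 0:
            if demand > 0:
                raise DegenerateInputError(
                    f"group {g.name!r} has zero production but is consumed"
                )
            continue
        EE[i] = demand / prod
        if EE[i] > 1.0 + EE_TOL:
            bad.append(f"{g.name} (EE={EE[i]:.4f})")
        M0[i] = PB[i] * max(1.0 - EE[i], 0.0)
    if bad:
        raise BalanceError(
            "mass balance violated, predation+catch exceed production for: "
            + ", ".join(bad)
        )

    # detrital inflow: unassimilated consumption + non-predation deaths
    det_idx = [i for i, g in enumerate(web.groups) if g.role == "detritus"]
    inflow_total = float((unassim * QB * B0).sum() + (M0 * B0).sum())
    det_inflow = np.zeros(len(det_idx))
    det_bad = []
    for k, i in enumerate(det_idx):
        # single-pool convention: if several detritus pools exist, inflow is
        # split in proportion to their baseline biomass
        share = B0[i] / B0[det_idx].sum() if B0[det_idx].sum() > 0 else 1.0
        det_inflow[k] = inflow_total * share
        consumed = Q0[i].sum()
        EE[i] = consumed / det_inflow[k] if det_inflow[k] > 0 else 0.0
        if EE[i] > 1.0 + EE_TOL:
            det_bad.append(f"{web.groups[i].name} (EE={EE[i]:.4f})")
    if det_bad:
        raise BalanceError(
            "detritus consumed faster than replenished: " + ", ".join(det_bad)
        )

    return BalancedWeb(web=web, EE=EE, Q0=Q0, M0=M0, detritus_inflow=det_inflow)


# -- CSV interchange ----------------------------------------------------------

GROUP_COLUMNS = [
    "name", "role", "B0", "PB", "QB", "unassim",
    "F0_commercial", "F0_recreational", "site_attachment",
    "wetland_associated", "guild",
]


def read_foodweb(groups_csv: str | Path, diet_csv: str | Path) -> FoodWeb:
    """Load a web from the standard two-table layout.

    ``groups.csv`` has one row per functional group (columns as in
    :data:`GROUP_COLUMNS`); ``diet.csv`` is long format with columns
    prey, predator, fraction.
    """
    gdf = pd.read_csv(groups_csv)
    missing = set(GROUP_COLUMNS) - set(gdf.columns)
    if missing:
        raise ValueError(f"groups table missing columns: {sorted(missing)}")
    groups = [
        FunctionalGroup(
            name=str(r["name"]),
            role=str(r["role"]),
            B0=float(r["B0"]),
            PB=float(r["PB"]),
            QB=float(r["QB"]),
            unassim=float(r["unassim"]),
            F0_commercial=float(r["F0_commercial"]),
            F0_recreational=float(r["F0_recreational"]),
            site_attachment=float(r["site_attachment"]),
            wetland_associated=bool(r["wetland_associated"]),
            guild=str(r["guild"]),
        )
        for _, r in gdf.iterrows()
    ]
    index = {g.name: i for i, g in enumerate(groups)}
    ddf = pd.read_csv(diet_csv)
    diet = np.zeros((len(groups), len(groups)))
    for _, r in ddf.iterrows():
        diet[index[str(r["prey"])], index[str(r["predator"])]] = float(r["fraction"])
    return FoodWeb(groups, diet)


def write_foodweb(web: FoodWeb, groups_csv: str | Path, diet_csv: str | Path) -> None:
    """Write a web to the two-table CSV layout (inverse of read_foodweb)."""
    rows = []
    for g in web.groups:
        rows.append({
            "name": g.name, "role": g.role, "B0": g.B0, "PB": g.PB, "QB": g.QB,
            "unassim": g.unassim, "F0_commercial": g.F0_commercial,
            "F0_recreational": g.F0_recreational,
            "site_attachment": g.site_attachment,
            "wetland_associated": g.wetland_associated, "guild": g.guild,
        })
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(groups_csv, index=False)
    links = []
    for j, pred in enumerate(web.names):
        for i, prey in enumerate(web.names):
            if web.diet[i, j] > 0:
                links.append({"prey": prey, "predator": pred,
                              "fraction": web.diet[i, j]})
    pd.DataFrame(links, columns=["prey", "predator", "fraction"]).to_csv(
        diet_csv, index=False
    )
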