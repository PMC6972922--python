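"""Experiment orchestration: scenario x strategy grids, ablations, reports.

A full experiment runs the dynamic foodweb model over every requested
(scenario, strategy) cell, computes the indicator change table, clusters
the 18 scenario end states obtained under the status-quo ("Low")
strategy, classifies indicators into winners/losers, and optionally runs
the two ablations: removing the marine-park network (protected fraction
set to zero) and removing the terrestrial coupling.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import management as mgmt
from .dynamics import (
    DynamicParams,
    ForcingSeries,
    TrajectorySet,
    calibrate_dynamics,
    simulate,
)
from .foodweb import BalancedWeb, FoodWeb, compute_ecopath_balance
from .fixture import kimberley_fixture
from .indicators import (
    ChangeTable,
    ClusterResult,
    IndicatorSet,
    bootstrap_support,
    classify_indicators,
    cluster_scenarios,
    scenario_distance_matrix,
)
from .scenarios import (
    GuildSensitivity,
    Scenario,
    build_climate_forcing,
    build_development_forcing,
    couple_terrestrial,
    enumerate_scenarios,
    parse_scenario_id,
)
from .synthetic import generate_terrestrial_drivers

__all__ = ["RunConfig", "ExperimentResults", "run_cell", "mpa_ablation",
           "run_experiment", "write_reports"]

logger = logging.getLogger(__name__)

#: the strategy the study treats as status quo
STATUS_QUO = "Low"


@dataclass
class RunConfig:
    """Configuration of one experiment.

    When `groups_csv`/`diet_csv` are unset the shipped analogue web and
    its indicator/sensitivity tables are used.
    """

    groups_csv: str | None = None
    diet_csv: str | None = None
    scenario_ids: list[str] | None = None      # None = full 18-scenario grid
    strategies: list[str] | None = None        # None = all five levels
    terrestrial_coupling: bool = True
    mpa_ablation: bool = False
    ablation_scenario: str = "HC-HD-dry"
    vulnerability: float = 1.5
    park_domain_fraction: float = 0.30
    step_months: int = 1
    n_boot: int = 0                            # bootstrap replicates (0 = skip)
    k_clusters: int = 3
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentResults:
    config: RunConfig
    trajectories: dict[tuple[str, str], TrajectorySet]
    change_table: ChangeTable | None = None
    cluster: ClusterResult | None = None
    classification: pd.DataFrame | None = None
    ablation: dict[str, TrajectorySet] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def run_cell(
    web: FoodWeb,
    bw: BalancedWeb,
    dp: DynamicParams,
    scenario: Scenario,
    strategy: str,
    sens: GuildSensitivity,
    terrestrial_coupling: bool = True,
    protected: bool = True,
    park_domain_fraction: float = 0.30,
    step_months: int = 1,
) -> TrajectorySet:
    """Simulate one (scenario, strategy) cell.

    Assembles climate, development, terrestrial and management forcing
    into a single ForcingSeries and integrates 2015-2050. With
    ``protected=False`` the spatial protection fraction is zeroed while
    everything else (including fishing caps) is kept, which is the
    with/without-MPA comparison arm.
    """
    drivers = generate_terrestrial_drivers(scenario)
    sp = mgmt.resolve_strategy(strategy)
    mods = mgmt.apply_strategy(
        sp, web, park_domain_fraction if protected else 0.0
    )
    if not protected:
        mods.protected_fraction[:] = 0.0
        # rebuild static factors without spatial refuge
        sigma0 = np.zeros(web.n)
        mods.commercial_factor = 1.0 - sigma0
        mods.recreational_factor = (1.0 - sigma0) * sp.recreational_multiplier

    climate = build_climate_forcing(scenario, sens, web)
    dev = build_development_forcing(
        scenario, drivers, web, bw.M0,
        tourism_mortality_cap=mods.tourism_mortality_cap,
        other_use_mortality_cap=mods.other_use_mortality_cap,
    )
    # management replaces the raw development fishing channel with the
    # capped, protection- and bag-adjusted one
    dev.channels["fishing_mortality"][:, :] = mgmt.fishing_channel(
        web, mods, scenario.development.tourism_growth
    )
    forcing = climate.combine(dev)
    if terrestrial_coupling:
        forcing = forcing.combine(couple_terrestrial(drivers, web))

    return simulate(
        dp, forcing, step_months=step_months,
        scenario_id=scenario.id, strategy_id=strategy,
    )


def mpa_ablation(
    web: FoodWeb,
    bw: BalancedWeb,
    dp: DynamicParams,
    scenario: Scenario,
    strategy: str,
    sens: GuildSensitivity,
    **kwargs,
) -> tuple[TrajectorySet, TrajectorySet]:
    """Paired runs differing only in the protected fraction (p vs 0)."""
    with_mpa = run_cell(web, bw, dp, scenario, strategy, sens,
                        protected=True, **kwargs)
    without_mpa = run_cell(web, bw, dp, scenario, strategy, sens,
                           protected=False, **kwargs)
    return with_mpa, without_mpa


def _load_inputs(rc: RunConfig):
    if rc.groups_csv is None:
        return kimberley_fixture()
    from .foodweb import read_foodweb
    web = read_foodweb(rc.groups_csv, rc.diet_csv)
    _, indicators, sens = kimberley_fixture()
    return web, indicators, sens


def run_experiment(rc: RunConfig) -> ExperimentResults:
    """Run the requested grid and derive all downstream products.

    Clustering and indicator classification use only the status-quo
    strategy runs; both are skipped (with a logged notice) when the
    status-quo scenario set is too small to support them.
    """
    web, indicators, sens = _load_inputs(rc)
    bw = compute_ecopath_balance(web)
    dp = calibrate_dynamics(bw, rc.vulnerability)

    scenarios = (enumerate_scenarios() if rc.scenario_ids is None
                 else [parse_scenario_id(s) for s in rc.scenario_ids])
    strategies = list(rc.strategies) if rc.strategies else list(mgmt.STRATEGY_LEVELS)
    if not scenarios or not strategies:
        raise ValueError("scenario and strategy subsets must be non-empty")

    res = ExperimentResults(config=rc, trajectories={})
    for sc in scenarios:
        for strat in strategies:
            try:
                ts = run_cell(
                    web, bw, dp, sc, strat, sens,
                    terrestrial_coupling=rc.terrestrial_coupling,
                    park_domain_fraction=rc.park_domain_fraction,
                    step_months=rc.step_months,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"integration failed in cell ({sc.id}, {strat}): {exc}"
                ) from exc
            res.trajectories[(sc.id, strat)] = ts
            for g in ts.floored_groups:
                res.log.append(f"WARNING floor ({sc.id},{strat}): {g}")

    sq_runs = {sid: ts for (sid, strat), ts in res.trajectories.items()
               if strat == STATUS_QUO}
    if len(sq_runs) >= 2:
        end_states = {sid: ts.end_state for sid, ts in sq_runs.items()}
        res.cluster = scenario_distance_matrix(end_states)
        cluster_scenarios(res.cluster, min(rc.k_clusters, len(sq_runs)))
        if rc.n_boot >= 100:
            res.cluster = bootstrap_support(
                end_states, n_boot=rc.n_boot, seed=rc.seed,
                k=min(rc.k_clusters, len(sq_runs)),
            )

        ratios = {}
        for sid, ts in sq_runs.items():
            b0, b1 = ts.biomass[:, 0], ts.end_state
            col = {}
            for ind in indicators.indicators:
                if ind.klass == "system":
                    col[ind.name] = indicators.value(ind, b1, baseline=b0)
                else:
                    v0 = indicators.value(ind, b0)
                    col[ind.name] = indicators.value(ind, b1) / v0 - 1.0
            ratios[sid] = col
        table = pd.DataFrame(ratios)
        biomass_rows = [i.name for i in indicators.biomass_indicators()]
        res.change_table = ChangeTable(table.loc[biomass_rows])
        res.classification = classify_indicators(res.change_table)
        # system-level rows are reported alongside but not classified
        res.change_table.ratios = table
    else:
        res.log.append("NOTICE clustering skipped: fewer than 2 status-quo runs")
        logger.info("clustering skipped: fewer than 2 status-quo runs")

    if rc.mpa_ablation:
        sc = parse_scenario_id(rc.ablation_scenario)
        with_mpa, without_mpa = mpa_ablation(
            web, bw, dp, sc, STATUS_QUO, sens,
            terrestrial_coupling=rc.terrestrial_coupling,
            step_months=rc.step_months,
        )
        res.ablation = {"with_mpa": with_mpa, "without_mpa": without_mpa}

    return res


def write_reports(res: ExperimentResults, outdir: str | Path) -> dict[str, str]:
    """Persist results as tidy CSV/JSON artifacts.

    Returns the manifest mapping file name -> sha256 checksum; the
    manifest itself is written as manifest.json. Re-running on the same
    results rewrites byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    if res.trajectories:
        frames = [ts.to_frame() for ts in res.trajectories.values()]
        _save("trajectories.csv",
              lambda p: pd.concat(frames, ignore_index=True).to_csv(p, index=False))
    if res.change_table is not None:
        # %.17g round-trips IEEE doubles exactly
        _save("change_table.csv",
              lambda p: res.change_table.ratios.to_csv(
                  p, index_label="indicator", float_format="%.17g"))
    if res.classification is not None:
        _save("classification.csv", lambda p: res.classification.to_csv(p))
    if res.cluster is not None:
        payload = {
            "labels": res.cluster.labels,
            "assignments": {str(k): v.tolist()
                            for k, v in res.cluster.assignments.items()},
            "distance": res.cluster.distance.tolist(),
            "support": (res.cluster.support.tolist()
                        if res.cluster.support is not None else None),
        }
        _save("clusters.json",
              lambda p: p.write_text(json.dumps(payload, indent=1)))
    if res.ablation:
        rows = []
        for arm, ts in res.ablation.items():
            for i, g in enumerate(ts.web.names):
                rows.append({"arm": arm, "group": g,
                             "end_biomass": ts.end_state[i]})
        _save("ablation.csv",
              lambda p: pd.DataFrame(rows).to_csv(p, index=False))

    if not manifest:  # nothing to report: write nothing
        return manifest
    meta = {"config": res.config.to_dict(), "config_hash": res.config.config_hash,
            "seed": res.config.seed, "log": res.log}
    _save("run_log.json", lambda p: p.write_text(json.dumps(meta, indent=1,
                                                            default=str)))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
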