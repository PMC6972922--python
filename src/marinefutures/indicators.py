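"""Indicator reporting: Total Divergence, scenario clustering, and
winner/loser classification.

Total Divergence compares two biomass vectors with the generalized
(unnormalized) Kullback-Leibler divergence

    TD(a, b) = sum_i [ a_i * ln(a_i / b_i) - a_i + b_i ]

which, unlike composition-only KL, also registers changes in overall
biomass: writing A = sum a, B = sum b and p, q for the compositions,
TD(a, b) = A * KL(p || q) + A * ln(A / B) + B - A. It is non-negative,
zero iff a = b, asymmetric, and homogeneous of degree one
(TD(c*a, c*b) = c * TD(a, b)).

Scenario end states are compared with the symmetrized divergence and
grouped by average-linkage hierarchical clustering; cluster stability is
assessed by bootstrap resampling of functional-group coordinates.
Indicators (biomass sums over member groups) are classified as winners
(change ratio positive in every scenario), losers (negative in every
scenario) or mixed, with scenario sensitivity measured by the range of
the change ratio across the ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "IndicatorSet",
    "Indicator",
    "ChangeTable",
    "ClusterResult",
    "total_divergence",
    "scenario_distance_matrix",
    "cluster_scenarios",
    "bootstrap_support",
    "classify_indicators",
]

logger = logging.getLogger(__name__)

INDICATOR_CLASSES = ("meta_group", "keystone", "charismatic", "habitat", "system")

#: floor substituted for non-positive biomass entries before taking logs
TD_FLOOR = 1e-12


@dataclass(frozen=True)
class Indicator:
    name: str
    klass: str
    member_groups: tuple[str, ...] = ()

    def __post_init__(self):
        if self.klass not in INDICATOR_CLASSES:
            raise ValueError(f"unknown indicator class {self.klass!r}")


class IndicatorSet:
    """Named biomass aggregates plus system-level functionals.

    Biomass indicators sum the biomass of their member groups; the
    system class holds scalar functionals of the whole state (Total
    Divergence from the 2015 state) rather than biomass sums.
    """

    def __init__(self, indicators: list[Indicator], group_names: list[str]):
        names = [ind.name for ind in indicators]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique")
        known = set(group_names)
        for ind in indicators:
            missing = set(ind.member_groups) - known
            if missing:
                raise ValueError(
                    f"indicator {ind.name!r} references unknown groups {missing}"
                )
            if ind.klass == "system" and ind.member_groups:
                raise ValueError("system indicators are functionals, not sums")
        self.indicators = list(indicators)
        self.group_names = list(group_names)

    @property
    def names(self) -> list[str]:
        return [ind.name for ind in self.indicators]

    def biomass_indicators(self) -> list[Indicator]:
        return [i for i in self.indicators if i.klass != "system"]

    def value(self, ind: Indicator, biomass: np.ndarray,
              baseline: np.ndarray | None = None) -> float:
        idx = [self.group_names.index(g) for g in ind.member_groups]
        if ind.klass == "system":
            if baseline is None:
                raise ValueError("system indicators need the baseline state")
            return total_divergence(biomass, baseline)
        return float(biomass[idx].sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_names: list[str]) -> "IndicatorSet":
        """Build from a tidy table with columns indicator, class, group."""
        inds = []
        for (name, klass), sub in df.groupby(["indicator", "class"], sort=False):
            members = tuple(g for g in sub["group"] if isinstance(g, str) and g)
            inds.append(Indicator(name, klass, members if klass != "system" else ()))
        return cls(inds, group_names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.indicators:
            if ind.member_groups:
                for g in ind.member_groups:
                    rows.append({"indicator": ind.name, "class": ind.klass,
                                 "group": g})
            else:
                rows.append({"indicator": ind.name, "class": ind.klass,
                             "group": ""})
        return pd.DataFrame(rows, columns=["indicator", "class", "group"])


@dataclass
class ChangeTable:
    """Per indicator x scenario change ratios rho = B(2050)/B(2015) - 1."""

    ratios: pd.DataFrame  # index: indicator, columns: scenario ids

    def __post_init__(self):
        vals = self.ratios.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("change ratios must be finite")
        if (vals <= -1).any():
            raise ValueError("change ratios must exceed -1")


@dataclass
class ClusterResult:
    distance: np.ndarray                      # (n, n) symmetric, zero diagonal
    labels: list[str]                         # scenario ids
    linkage_tree: np.ndarray | None = None
    assignments: dict[int, np.ndarray] = field(default_factory=dict)  # k -> labels
    support: np.ndarray | None = None         # bootstrap co-assignment


def total_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Generalized I-divergence between two positive biomass vectors.

    Non-positive entries are replaced by a small floor (with a logged
    note) so that transiently extirpated groups do not produce infinities.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if (a <= 0).any() or (b <= 0).any():
        logger.info("total_divergence: flooring non-positive entries at %g",
                    TD_FLOOR)
        a = np.maximum(a, TD_FLOOR)
        b = np.maximum(b, TD_FLOOR)
    return float(np.sum(a * np.log(a / b) - a + b))


def scenario_distance_matrix(
    end_states: dict[str, np.ndarray] | list[np.ndarray],
    labels: list[str] | None = None,
) -> ClusterResult:
    """Symmetrized Total Divergence between scenario end states.

    d(s, s') = (TD(s, s') + TD(s', s)) / 2.
    """
    if isinstance(end_states, dict):
        labels = list(end_states.keys())
        states = [np.asarray(v, dtype=float) for v in end_states.values()]
    else:
        states = [np.asarray(v, dtype=float) for v in end_states]
        labels = labels or [str(i) for i in range(len(states))]
    n = len(states)
    if n < 2:
        raise ValueError("need at least two end states")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.5 * (total_divergence(states[i], states[j])
                       + total_divergence(states[j], states[i]))
            D[i, j] = D[j, i] = d
    return ClusterResult(distance=D, labels=labels)


def cluster_scenarios(cr: ClusterResult, k: int) -> np.ndarray:
    """Average-linkage agglomerative clustering cut at k clusters.

    Returns integer cluster labels (1..k) aligned with cr.labels; the
    linkage tree is stored on the result. Ties are resolved by the
    linkage algorithm's stable lowest-index merge order.
    """
    n = len(cr.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    if cr.linkage_tree is None:
        cr.linkage_tree = linkage(squareform(cr.distance, checks=False),
                                  method="average")
    assign = fcluster(cr.linkage_tree, t=k, criterion="maxclust")
    cr.assignments[k] = assign
    return assign


def bootstrap_support(
    end_states: dict[str, np.ndarray],
    n_boot: int = 200,
    seed: int | None = None,
    k: int = 3,
    max_redraws: int = 100,
) -> ClusterResult:
    """Co-assignment support for the k-cluster partition.

    Functional-group coordinates are resampled with replacement; each
    replicate's symmetrized-divergence matrix is re-clustered at k and
    support(s, s') is the fraction of replicates in which s and s'
    fall in the same cluster. Degenerate resamples (a single distinct
    coordinate) are redrawn, up to `max_redraws` per replicate.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable support values")
    rng = np.random.default_rng(seed)
    labels = list(end_states.keys())
    X = np.stack([end_states[s] for s in labels])  # (n_scen, n_groups)
    n_scen, n_groups = X.shape
    co = np.zeros((n_scen, n_scen))
    for _ in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n_groups, size=n_groups)
            if len(np.unique(idx)) > 1:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        rep = scenario_distance_matrix([X[s, idx] for s in range(n_scen)],
                                       labels=labels)
        assign = cluster_scenarios(rep, k)
        co += assign[:, None] == assign[None, :]
    co /= n_boot
    base = scenario_distance_matrix({s: end_states[s] for s in labels})
    cluster_scenarios(base, k)
    base.support = co
    return base


def classify_indicators(
    ct: ChangeTable, sensitivity_threshold: float = 0.5
) -> pd.DataFrame:
    """Winner/loser/mixed status and scenario sensitivity per indicator.

    An indicator is a winner if its change ratio is positive in every
    scenario, a loser if negative in every scenario, otherwise mixed.
    Sensitivity is the range of the ratio across scenarios, labelled
    high above the threshold. The returned table carries median ratio
    (winners-losers axis) and range (sensitivity axis) for the two-axis
    placement of indicators.
    """
    if ct.ratios.shape[1] < 2:
        raise ValueError("need at least two scenarios to classify")
    rows = []
    for name, row in ct.ratios.iterrows():
        vals = row.to_numpy(dtype=float)
        if vals.min() > 0:
            status = "winner"
        elif vals.max() < 0:
            status = "loser"
        else:
            status = "mixed"
        rng_ = float(vals.max() - vals.min())
        rows.append({
            "indicator": name,
            "status": status,
            "median_ratio": float(np.median(vals)),
            "range": rng_,
            "sensitivity": "high" if rng_ > sensitivity_threshold else "low",
        })
    return pd.DataFrame(rows).set_index("indicator")
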