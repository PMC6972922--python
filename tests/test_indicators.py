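import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marinefutures import (
    ChangeTable,
    Indicator,
    IndicatorSet,
    bootstrap_support,
    classify_indicators,
    cluster_scenarios,
    scenario_distance_matrix,
    total_divergence,
)

positive_vectors = st.integers(3, 10).flatmap(
    lambda n: st.lists(
        st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
        min_size=n, max_size=n,
    )
)


def td_brute(a, b):
    """Element-by-element oracle for the generalized I-divergence."""
    return sum(x * math.log(x / y) - x + y for x, y in zip(a, b))


class TestTotalDivergence:
    def test_identity_gives_zero(self):
        a = np.array([3.0, 1.5, 0.7])
        assert total_divergence(a, a) == 0.0

    def test_hand_computed_values_and_asymmetry(self):
        a, b = np.array([2.0, 2.0]), np.array([1.0, 1.0])
        assert total_divergence(a, b) == pytest.approx(2 * (2 * math.log(2) - 1))
        assert total_divergence(a, b) == pytest.approx(0.7726, abs=1e-4)
        assert total_divergence(b, a) == pytest.approx(2 * (1 - math.log(2)))
        assert total_divergence(b, a) == pytest.approx(0.6137, abs=1e-4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive_vectors, st.data())
    def test_matches_brute_force_oracle(self, a, data):
        b = data.draw(st.lists(st.floats(1e-3, 1e3), min_size=len(a),
                               max_size=len(a)))
        av, bv = np.array(a), np.array(b)
        assert total_divergence(av, bv) == pytest.approx(td_brute(a, b),
                                                         abs=1e-12, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive_vectors, st.data())
    def test_nonnegative_with_equality_iff_equal(self, a, data):
        b = data.draw(st.lists(st.floats(1e-3, 1e3), min_size=len(a),
                               max_size=len(a)))
        av, bv = np.array(a), np.array(b)
        td = total_divergence(av, bv)
        assert td >= 0.0
        if not np.array_equal(av, bv):
            assert td > 0.0 or np.allclose(av, bv)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(positive_vectors, st.floats(0.01, 100.0))
    def test_homogeneous_of_degree_one(self, a, c):
        av = np.array(a)
        bv = av[::-1].copy() + 0.5
        assert total_divergence(c * av, c * bv) == pytest.approx(
            c * total_divergence(av, bv), rel=1e-9
        )

    def test_registers_total_biomass_change(self):
        # unlike composition-only KL, scaling one vector is seen
        a = np.array([1.0, 2.0, 3.0])
        assert total_divergence(a, 2 * a) > 0.0
        assert total_divergence(2 * a, a) > 0.0

    def test_nonpositive_entries_floored(self, caplog):
        a = np.array([1.0, 0.0])
        b = np.array([1.0, 1.0])
        td = total_divergence(a, b)
        assert np.isfinite(td) and td > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_divergence(np.ones(3), np.ones(4))


class TestDistanceMatrix:
    def test_identical_states_give_zero_matrix(self):
        states = {f"s{i}": np.array([1.0, 2.0, 3.0]) for i in range(4)}
        cr = scenario_distance_matrix(states)
        np.testing.assert_array_equal(cr.distance, 0.0)

    def test_symmetrization_averages_both_directions(self):
        cr = scenario_distance_matrix(
            {"a": np.array([2.0, 2.0]), "b": np.array([1.0, 1.0])}
        )
        expected = 0.5 * (2 * (2 * math.log(2) - 1) + 2 * (1 - math.log(2)))
        assert cr.distance[0, 1] == pytest.approx(expected)
        assert cr.distance[0, 1] == pytest.approx(0.6931, abs=1e-4)
        assert cr.distance[1, 0] == cr.distance[0, 1]
        assert cr.distance[0, 0] == 0.0

    def test_eighteen_states_shape_and_pair_count(self):
        rng = np.random.default_rng(0)
        states = {f"s{i}": rng.uniform(0.5, 5, 12) for i in range(18)}
        cr = scenario_distance_matrix(states)
        assert cr.distance.shape == (18, 18)
        iu = np.triu_indices(18, 1)
        assert len(cr.distance[iu]) == 153

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            scenario_distance_matrix({"only": np.ones(3)})


def two_blob_states(rng, n_per_blob=3, n_groups=8):
    states = {}
    for i in range(n_per_blob):
        states[f"a{i}"] = 1.0 + 0.01 * rng.random(n_groups)
        states[f"b{i}"] = 10.0 + 0.01 * rng.random(n_groups)
    return states


class TestClustering:
    def test_recovers_well_separated_blobs(self):
        states = two_blob_states(np.random.default_rng(1))
        cr = scenario_distance_matrix(states)
        assign = cluster_scenarios(cr, 2)
        blob_a = {assign[i] for i, s in enumerate(cr.labels) if s.startswith("a")}
        blob_b = {assign[i] for i, s in enumerate(cr.labels) if s.startswith("b")}
        assert len(blob_a) == 1 and len(blob_b) == 1 and blob_a != blob_b

    def test_k_equals_n_gives_singletons(self):
        states = two_blob_states(np.random.default_rng(2))
        cr = scenario_distance_matrix(states)
        assign = cluster_scenarios(cr, len(states))
        assert len(set(assign)) == len(states)

    def test_k_out_of_range_rejected(self):
        cr = scenario_distance_matrix({"a": np.ones(3), "b": 2 * np.ones(3)})
        with pytest.raises(ValueError):
            cluster_scenarios(cr, 0)
        with pytest.raises(ValueError):
            cluster_scenarios(cr, 3)

    def test_relabeling_permutes_assignments_consistently(self):
        rng = np.random.default_rng(3)
        states = {f"s{i}": rng.uniform(0.5, 5, 10) for i in range(6)}
        cr = scenario_distance_matrix(states)
        assign = cluster_scenarios(cr, 3)
        order = list(states)[::-1]
        cr2 = scenario_distance_matrix({s: states[s] for s in order})
        assign2 = cluster_scenarios(cr2, 3)
        # same partition of scenario ids under both orderings
        def partition(labels, a):
            groups = {}
            for lab, c in zip(labels, a):
                groups.setdefault(c, set()).add(lab)
            return {frozenset(v) for v in groups.values()}
        assert partition(cr.labels, assign) == partition(cr2.labels, assign2)


class TestBootstrapSupport:
    def test_identical_scenarios_fully_supported(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 3, 10)
        states = {"a": base.copy(), "b": base.copy(),
                  "c": 10 * base, "d": 11 * base}
        cr = bootstrap_support(states, n_boot=100, seed=0, k=2)
        assert cr.support[0, 1] == 1.0

    def test_blob_support_high_within_blobs(self):
        states = two_blob_states(np.random.default_rng(5))
        cr = bootstrap_support(states, n_boot=200, seed=1, k=2)
        labels = cr.labels
        for i, si in enumerate(labels):
            for j, sj in enumerate(labels):
                if i < j and si[0] == sj[0]:
                    assert cr.support[i, j] > 0.95

    def test_deterministic_under_fixed_seed(self):
        states = two_blob_states(np.random.default_rng(6))
        a = bootstrap_support(states, n_boot=100, seed=7, k=2)
        b = bootstrap_support(states, n_boot=100, seed=7, k=2)
        np.testing.assert_array_equal(a.support, b.support)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": np.ones(3), "b": np.ones(3)}, n_boot=10)


class TestIndicatorSet:
    def test_membership_validated(self):
        with pytest.raises(ValueError, match="unknown groups"):
            IndicatorSet([Indicator("x", "habitat", ("nope",))], ["a", "b"])

    def test_biomass_aggregation_and_system_functional(self):
        iset = IndicatorSet(
            [Indicator("pair", "meta_group", ("a", "c")),
             Indicator("div", "system")],
            ["a", "b", "c"],
        )
        b = np.array([1.0, 2.0, 3.0])
        assert iset.value(iset.indicators[0], b) == 4.0
        assert iset.value(iset.indicators[1], b, baseline=b) == 0.0

    def test_frame_round_trip(self):
        iset = IndicatorSet(
            [Indicator("pair", "meta_group", ("a", "c")),
             Indicator("div", "system")],
            ["a", "b", "c"],
        )
        back = IndicatorSet.from_frame(iset.to_frame(), ["a", "b", "c"])
        assert back.names == iset.names


class TestClassification:
    def _table(self, rows):
        return ChangeTable(pd.DataFrame(rows, columns=["s1", "s2", "s3"]))

    def test_winner_loser_mixed_and_sensitivity(self):
        ct = self._table({
            "up": [0.1, 0.3, 0.2],
            "down": [-0.6, -0.1, -0.8],
            "both": [-0.1, 0.2, 0.0],
        }.values())
        ct.ratios.index = ["up", "down", "both"]
        out = classify_indicators(ct, sensitivity_threshold=0.5)
        assert out.loc["up", "status"] == "winner"
        assert out.loc["up", "sensitivity"] == "low"
        assert out.loc["up", "range"] == pytest.approx(0.2)
        assert out.loc["down", "status"] == "loser"
        assert out.loc["down", "sensitivity"] == "high"
        assert out.loc["both", "status"] == "mixed"

    def test_invariant_to_scenario_ordering(self):
        df = pd.DataFrame({"s1": [0.1, -0.2], "s2": [0.4, -0.1]},
                          index=["a", "b"])
        out1 = classify_indicators(ChangeTable(df))
        out2 = classify_indicators(ChangeTable(df[["s2", "s1"]]))
        pd.testing.assert_frame_equal(out1, out2)

    def test_single_scenario_rejected(self):
        with pytest.raises(ValueError):
            classify_indicators(ChangeTable(pd.DataFrame({"s": [0.1]},
                                                         index=["a"])))

    def test_ratio_bounds_validated(self):
        with pytest.raises(ValueError):
            ChangeTable(pd.DataFrame({"s1": [-1.2], "s2": [0.0]}, index=["a"]))
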