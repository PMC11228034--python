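"""Connectivity-matrix assembly, aggregation, summaries and matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from calyxwire import (
    ConnectivityMatrix,
    NeuronRecord,
    SynapseEdge,
    TypeMap,
    aggregate_by_type,
    build_matrix,
    greedy_one_to_one_matching,
    summarize_inputs,
)


class TestBuildMatrix:
    def test_threshold_boundary_retains_only_at_or_above(self):
        edges = [SynapseEdge("A", "K1", 6), SynapseEdge("B", "K1", 4)]
        m = build_matrix(edges, {"A", "B"}, {"K1"}, threshold=5)
        assert m.to_frame().loc["A", "K1"] == 6
        assert m.to_frame().loc["B", "K1"] == 0

    def test_empty_edge_list_gives_zero_matrix(self):
        m = build_matrix([], {"A", "B"}, {"K1", "K2"}, threshold=5)
        assert m.shape == (2, 2)
        assert not m.W.any()

    def test_counts_kept_verbatim_above_threshold(self):
        edges = [
            SynapseEdge("A", "K1", 6),
            SynapseEdge("A", "K2", 9),
            SynapseEdge("B", "K2", 5),
        ]
        m = build_matrix(edges, {"A", "B"}, {"K1", "K2"}, threshold=5)
        assert m.to_frame().values.tolist() == [[6.0, 9.0], [0.0, 5.0]]

    def test_duplicate_edges_rejected(self):
        edges = [SynapseEdge("A", "K1", 6), SynapseEdge("A", "K1", 7)]
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(edges, {"A"}, {"K1"}, threshold=5)

    def test_edges_outside_axes_ignored(self):
        edges = [SynapseEdge("A", "K1", 6), SynapseEdge("X", "K1", 50)]
        m = build_matrix(edges, {"A"}, {"K1"}, threshold=5)
        assert m.to_frame().values.tolist() == [[6.0]]

    def test_idempotent_under_rethreshold(self, small_matrix):
        edges = [
            SynapseEdge(i, o, int(small_matrix.W[a, b]))
            for a, i in enumerate(small_matrix.input_ids)
            for b, o in enumerate(small_matrix.output_ids)
            if small_matrix.W[a, b] > 0
        ]
        again = build_matrix(
            edges,
            small_matrix.input_ids,
            small_matrix.output_ids,
            threshold=small_matrix.threshold,
        )
        np.testing.assert_array_equal(again.W, small_matrix.W)

    def test_ids_ordered_lexicographically(self):
        m = build_matrix([], {"b", "a", "c"}, {"z", "y"}, threshold=0)
        assert m.input_ids == ["a", "b", "c"]
        assert m.output_ids == ["y", "z"]


class TestAggregateByType:
    def test_mean_over_same_type(self):
        edges = [SynapseEdge("v1", "K1", 5), SynapseEdge("v2", "K1", 7)]
        m = build_matrix(edges, {"v1", "v2"}, {"K1"}, threshold=5)
        agg = aggregate_by_type(m, TypeMap({"v1": "aMe12", "v2": "aMe12"}, "mean"))
        assert agg.to_frame().loc["aMe12", "K1"] == 6

    def test_sum_over_same_type(self):
        edges = [SynapseEdge("v1", "K1", 5), SynapseEdge("v2", "K1", 7)]
        m = build_matrix(edges, {"v1", "v2"}, {"K1"}, threshold=5)
        agg = aggregate_by_type(m, TypeMap({"v1": "t", "v2": "t"}, "sum"))
        assert agg.to_frame().loc["t", "K1"] == 12

    def test_identity_map_is_reordering_only(self, small_matrix):
        tmap = TypeMap({i: i for i in small_matrix.input_ids}, "sum")
        agg = aggregate_by_type(small_matrix, tmap)
        pd.testing.assert_frame_equal(agg.to_frame(), small_matrix.to_frame())

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            TypeMap({"a": "t"}, mode="median")

    def test_uncovered_input_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            aggregate_by_type(small_matrix, TypeMap({"A": "t"}, "sum"))

    def test_threshold_never_resurrected_by_aggregation(self):
        # Two sub-threshold edges from same-type inputs must not combine
        # into a retained connection.
        edges = [SynapseEdge("v1", "K1", 3), SynapseEdge("v2", "K1", 4)]
        m = build_matrix(edges, {"v1", "v2"}, {"K1"}, threshold=5)
        agg = aggregate_by_type(m, TypeMap({"v1": "t", "v2": "t"}, "sum"))
        assert agg.to_frame().loc["t", "K1"] == 0


class TestSummarizeInputs:
    def test_group_synapse_fractions(self):
        edges = [SynapseEdge("A", "K1", 10), SynapseEdge("B", "K1", 30)]
        m = build_matrix(edges, {"A", "B"}, {"K1"}, threshold=5)
        s = summarize_inputs(m, {"A": "VPN", "B": "LVIN"})
        assert s.group_table.loc["VPN", "synapse_fraction"] == pytest.approx(0.25)
        assert s.group_table.loc["LVIN", "synapse_fraction"] == pytest.approx(0.75)

    def test_fractions_sum_to_one(self, default_wiring):
        m, _ = default_wiring
        groups = {i: ("VPN" if a % 2 else "LVIN") for a, i in enumerate(m.input_ids)}
        s = summarize_inputs(m, groups)
        assert s.group_table["synapse_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        # per-output composition rows each sum to 1 as well
        np.testing.assert_allclose(s.output_composition.sum(axis=1), 1.0, atol=1e-12)

    def test_unconnected_output_excluded_from_composition(self):
        edges = [SynapseEdge("A", "K1", 6)]
        m = build_matrix(edges, {"A"}, {"K1", "K2"}, threshold=5)
        s = summarize_inputs(m, {"A": "VPN"})
        assert list(s.output_composition.index) == ["K1"]
        assert s.n_connected_outputs == 1

    def test_pct_outputs_contacted(self):
        edges = [SynapseEdge("A", f"K{j}", 6) for j in range(3)]
        m = build_matrix(edges, {"A"}, {f"K{j}" for j in range(10)}, threshold=5)
        s = summarize_inputs(m, {"A": "VPN"})
        assert s.input_ranking.loc[0, "pct_outputs_contacted"] == pytest.approx(30.0)

    def test_ranking_descending_with_id_ties(self):
        edges = [
            SynapseEdge("b", "K1", 7),
            SynapseEdge("a", "K1", 7),
            SynapseEdge("c", "K1", 9),
        ]
        m = build_matrix(edges, {"a", "b", "c"}, {"K1"}, threshold=5)
        s = summarize_inputs(m, {i: "g" for i in "abc"})
        assert list(s.input_ranking["input_id"]) == ["c", "a", "b"]


def _greedy_oracle(scores: pd.DataFrame) -> dict[str, str]:
    """Brute force: process claims in globally descending score order."""
    rows = scores.sort_values(
        ["score", "query_id", "target_id"], ascending=[False, True, True]
    )
    taken, assigned = set(), {}
    for r in rows.itertuples():
        if r.query_id in assigned or r.target_id in taken:
            continue
        assigned[r.query_id] = r.target_id
        taken.add(r.target_id)
    for q in scores["query_id"].unique():
        assigned.setdefault(q, "unmatched")
    return assigned


class TestGreedyMatching:
    def test_conflict_resolved_by_stronger_score(self):
        scores = pd.DataFrame(
            {
                "query_id": ["q1", "q1", "q2", "q2"],
                "target_id": ["t1", "t2", "t1", "t2"],
                "score": [0.9, 0.3, 0.8, 0.7],
            }
        )
        assert greedy_one_to_one_matching(scores) == {"q1": "t1", "q2": "t2"}
        assert _greedy_oracle(scores) == {"q1": "t1", "q2": "t2"}

    def test_non_conflicting_equals_argmax(self):
        scores = pd.DataFrame(
            {
                "query_id": ["q1", "q1", "q2", "q2"],
                "target_id": ["t1", "t2", "t1", "t2"],
                "score": [0.9, 0.3, 0.2, 0.7],
            }
        )
        assert greedy_one_to_one_matching(scores) == {"q1": "t1", "q2": "t2"}

    def test_single_pair(self):
        scores = pd.DataFrame(
            {"query_id": ["q"], "target_id": ["t"], "score": [0.5]}
        )
        assert greedy_one_to_one_matching(scores) == {"q": "t"}

    def test_exhausted_query_unmatched(self):
        scores = pd.DataFrame(
            {
                "query_id": ["q1", "q2"],
                "target_id": ["t1", "t1"],
                "score": [0.9, 0.8],
            }
        )
        assert greedy_one_to_one_matching(scores) == {"q1": "t1", "q2": "unmatched"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_descending_score_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        queries = [f"q{i}" for i in range(5)]
        targets = [f"t{i}" for i in range(4)]
        rows = [
            (q, t, float(rng.random()))
            for q, t in itertools.product(queries, targets)
        ]
        scores = pd.DataFrame(rows, columns=["query_id", "target_id", "score"])
        assert greedy_one_to_one_matching(scores) == _greedy_oracle(scores)

    @pytest.mark.parametrize("seed", range(4))
    def test_injective_and_row_order_invariant(self, seed):
        rng = np.random.default_rng(100 + seed)
        rows = [
            (f"q{i}", f"t{j}", float(rng.random()))
            for i in range(6)
            for j in range(6)
        ]
        scores = pd.DataFrame(rows, columns=["query_id", "target_id", "score"])
        base = greedy_one_to_one_matching(scores)
        matched = [t for t in base.values() if t != "unmatched"]
        assert len(matched) == len(set(matched))
        shuffled = scores.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert greedy_one_to_one_matching(shuffled) == base


class TestRecords:
    def test_neuropil_only_for_vpn(self):
        with pytest.raises(ValueError, match="neuropil"):
            NeuronRecord("n1", super_class="KC", neuropil_origin="Me")
        NeuronRecord("n2", super_class="VPN", neuropil_origin="Me")

    def test_edge_location_count_consistency(self):
        with pytest.raises(ValueError, match="locations"):
            SynapseEdge("a", "b", 2, locations=(((0.0, 0.0, 0.0)),))

    def test_binarized_flag_requires_binary_entries(self):
        with pytest.raises(ValueError, match="binarized"):
            ConnectivityMatrix(["a"], ["k"], np.array([[2.0]]), binarized=True)
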