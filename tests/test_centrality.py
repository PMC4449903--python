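"""Centralities against hand-derived values and brute-force enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    brute_betweenness,
    brute_closeness,
    random_digraph,
    symmetrize,
)
from thrombonet import (
    CentralityRecord,
    ProteinNetwork,
    SummaryError,
    betweenness_all,
    closeness_all,
    compare_groups,
    degree_all,
    extract_hubs,
    centrality_table,
    summarize,
)
from thrombonet.datasets import THROMBOSIS_HUB_TABLE


def net_from(edges, extra_nodes=()):
    return ProteinNetwork.from_edges(edges, extra_nodes=extra_nodes)


class TestDegree:
    def test_path3(self, path3):
        assert degree_all(path3) == {"A": 1, "B": 2, "C": 1}

    def test_bidirectional_pair_counts_once(self):
        net = net_from([("A", "B"), ("B", "A")])
        assert degree_all(net) == {"A": 1, "B": 1}

    def test_star_hub(self, star5_out):
        assert degree_all(star5_out)["H"] == 4

    def test_degree_conservation(self, twin_cliques):
        # sum of degrees = 2 * number of unordered adjacent pairs
        deg = degree_all(twin_cliques)
        pairs = {frozenset(e) for e in twin_cliques.edges}
        assert sum(deg.values()) == 2 * len(pairs)


class TestBetweenness:
    def test_path3_directed(self, path3):
        assert betweenness_all(path3) == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_path4_directed(self, path4):
        bet = betweenness_all(path4)
        assert bet["B"] == 2.0 and bet["C"] == 2.0

    def test_complete_bidirectional_graph_all_zero(self, clique4):
        assert set(betweenness_all(clique4).values()) == {0.0}

    def test_leaves_have_zero_betweenness(self, star5_out):
        bet = betweenness_all(star5_out)
        assert all(bet[f"L{i}"] == 0.0 for i in range(1, 5))

    def test_undirected_mode_uses_ordered_pairs(self, path3):
        # pairs (A,C) and (C,A) both pass through B
        assert betweenness_all(path3, "undirected")["B"] == 2.0


class TestCloseness:
    def test_isolated_node_is_zero(self):
        net = net_from([("A", "B")], extra_nodes=["Z"])
        assert closeness_all(net)["Z"] == 0.0

    def test_path3_directed(self, path3):
        assert closeness_all(path3) == {"A": 1.5, "B": 1.0, "C": 0.0}

    def test_clique_all_ones(self, clique4):
        assert set(closeness_all(clique4).values()) == {1.0}


class TestOracleEquivalence:
    """Implementation vs independent all-path enumeration."""

    @pytest.mark.parametrize("mode", ["directed", "undirected"])
    def test_random_digraphs_match_brute_force(self, mode):
        rng = np.random.default_rng(20250301)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            edges = random_digraph(n, 2.2 / n, rng)
            nodes = [f"n{i}" for i in range(n)]
            named = {(f"n{i}", f"n{j}") for i, j in edges}
            net = ProteinNetwork.from_edges(named, extra_nodes=nodes)
            check = named if mode == "directed" else symmetrize(named)
            bb = brute_betweenness(nodes, check)
            bc = brute_closeness(nodes, check)
            bet = betweenness_all(net, mode)
            clo = closeness_all(net, mode)
            for v in nodes:
                assert bet[v] == pytest.approx(bb[v], abs=1e-9)
                assert clo[v] == pytest.approx(bc[v], abs=1e-9)


@settings(derandomize=True, max_examples=40)
@given(
    st.sets(
        st.tuples(st.integers(0, 6), st.integers(0, 6)).filter(lambda e: e[0] != e[1]),
        max_size=15,
    ),
    st.permutations(list(range(7))),
)
def test_undirected_centralities_invariant_under_relabeling(edges, perm):
    nodes = [f"n{i}" for i in range(7)]
    named = {(f"n{i}", f"n{j}") for i, j in edges}
    relabeled = {(f"n{perm[i]}", f"n{perm[j]}") for i, j in edges}
    a = ProteinNetwork.from_edges(named, extra_nodes=nodes)
    b = ProteinNetwork.from_edges(relabeled, extra_nodes=nodes)
    for fn in (betweenness_all, closeness_all):
        va, vb = fn(a, "undirected"), fn(b, "undirected")
        for i in range(7):
            assert va[f"n{i}"] == pytest.approx(vb[f"n{perm[i]}"], abs=1e-9)


class TestSummarize:
    def test_average_degree_is_edge_node_ratio(self):
        # ring of 149 nodes plus chords to reach exactly 414 directed edges
        nodes = [f"p{i:03d}" for i in range(149)]
        edges = {(nodes[i], nodes[(i + 1) % 149]) for i in range(149)}
        span = 2
        while len(edges) < 414:
            for i in range(149):
                edges.add((nodes[i], nodes[(i + span) % 149]))
                if len(edges) == 414:
                    break
            span += 1
        net = ProteinNetwork.from_edges(edges)
        s = summarize(net)
        assert (s.n_nodes, s.n_edges) == (149, 414)
        assert round(s.average_degree, 2) == 2.78

    def test_path3_average_shortest_path(self, path3):
        assert summarize(path3).average_shortest_path == pytest.approx(4 / 3)

    def test_single_node_network(self):
        net = ProteinNetwork(frozenset(["A"]), frozenset())
        s = summarize(net)
        assert s.n_components == 1 and s.average_degree == 0.0

    def test_empty_network_raises(self):
        with pytest.raises(SummaryError):
            summarize(ProteinNetwork(frozenset(), frozenset()))


def make_record(node, degree, bet=0.0, clo=0.0, multi=False):
    return CentralityRecord(
        node=node, degree=degree, betweenness=bet, closeness=clo,
        functions=frozenset({"platelet"}), is_multifunctional=multi, is_hub=False,
    )


class TestExtractHubs:
    def test_threshold_filters_and_sorts(self):
        recs = [make_record(n, d) for n, d in [("w", 3), ("x", 25), ("y", 19), ("z", 23)]]
        assert [r.node for r in extract_hubs(recs, 10)] == ["x", "z", "y"]

    def test_threshold_zero_returns_all(self):
        recs = [make_record(n, d) for n, d in [("a", 0), ("b", 1)]]
        assert len(extract_hubs(recs, 0)) == 2

    def test_degree_equal_to_threshold_included(self):
        recs = [make_record(n, d) for n, d in [("a", 10), ("b", 10), ("c", 9)]]
        assert [r.node for r in extract_hubs(recs, 10)] == ["a", "b"]


class TestCompareGroups:
    def test_published_hub_table_group_means(self):
        """On the published 27-hub table, the four multifunctional
        proteins average betweenness 1860.25 vs 9712/23 for the rest."""
        cmp = compare_groups(THROMBOSIS_HUB_TABLE)
        assert cmp.group_sizes == {"multifunctional": 4, "nonmultifunctional": 23}
        assert cmp.group_means["multifunctional"]["betweenness"] == pytest.approx(1860.25)
        assert cmp.group_means["nonmultifunctional"]["betweenness"] == pytest.approx(9712 / 23)
        assert (
            cmp.group_means["multifunctional"]["betweenness"]
            > cmp.group_means["nonmultifunctional"]["betweenness"]
        )

    def test_identical_records_give_equal_means(self):
        recs = [make_record("a", 5, 1.0, 2.0, True), make_record("b", 5, 1.0, 2.0, False)]
        cmp = compare_groups(recs)
        assert cmp.group_means["multifunctional"] == cmp.group_means["nonmultifunctional"]

    def test_empty_group_flagged_not_raised(self):
        cmp = compare_groups([make_record("a", 1)])
        assert cmp.empty_groups == ("multifunctional",)
        assert math.isnan(cmp.group_means["multifunctional"]["degree"])


class TestCentralityTable:
    def test_ranked_by_degree_then_name(self, star5_out):
        recs = centrality_table(star5_out, hub_threshold=4)
        assert [r.node for r in recs] == ["H", "L1", "L2", "L3", "L4"]
        assert recs[0].is_hub and not recs[1].is_hub
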