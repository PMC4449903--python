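"""Modularity, Louvain recovery, and modular hubs."""

import networkx as nx
import numpy as np
import pytest

from oracles import best_modularity_partition
from thrombonet import (
    PartitionError,
    ProteinNetwork,
    build_network,
    ElementaryReaction,
    louvain,
    modular_hubs,
    modularity_score,
)


def blocks(partition):
    out = {}
    for node, module in partition.assignment.items():
        out.setdefault(module, set()).add(node)
    return sorted((tuple(sorted(b)) for b in out.values()))


class TestModularityScore:
    def test_one_module_clique_is_zero(self, clique4):
        assert modularity_score(clique4, {n: 1 for n in clique4.nodes}) == pytest.approx(0.0)

    def test_twin_cliques_planted_split(self, twin_cliques):
        assignment = {n: (1 if n.startswith("L") else 2) for n in twin_cliques.nodes}
        # direct formula: m=13, each side e_c=6, d_c=13
        assert modularity_score(twin_cliques, assignment) == pytest.approx(
            2 * (6 / 13 - (13 / 26) ** 2), abs=1e-4
        )
        assert modularity_score(twin_cliques, assignment) == pytest.approx(0.4231, abs=1e-4)

    def test_singleton_partition_is_negative(self, clique4):
        # Q = 0 - 4*(3/12)^2 = -0.25, agreeing with networkx
        assignment = {n: i for i, n in enumerate(sorted(clique4.nodes))}
        q = modularity_score(clique4, assignment)
        assert q == pytest.approx(-0.25)
        g = clique4.to_undirected_graph()
        assert q == pytest.approx(
            nx.community.modularity(g, [{n} for n in clique4.nodes])
        )
        assert q < 0

    def test_matches_networkx_on_random_partitions(self, twin_cliques):
        rng = np.random.default_rng(8)
        g = twin_cliques.to_undirected_graph()
        nodes = sorted(twin_cliques.nodes)
        for _ in range(20):
            labels = rng.integers(0, 3, len(nodes))
            assignment = dict(zip(nodes, (int(x) for x in labels)))
            comms = [
                {n for n in nodes if assignment[n] == c} for c in set(labels.tolist())
            ]
            assert modularity_score(twin_cliques, assignment) == pytest.approx(
                nx.community.modularity(g, comms), abs=1e-12
            )

    def test_partial_assignment_names_missing_nodes(self, clique4):
        with pytest.raises(PartitionError, match="D"):
            modularity_score(clique4, {"A": 1, "B": 1, "C": 1})


class TestLouvain:
    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_twin_cliques_recovered_for_any_seed(self, twin_cliques, seed):
        partition = louvain(twin_cliques, seed=seed)
        assert blocks(partition) == [
            ("L1", "L2", "L3", "L4"),
            ("R1", "R2", "R3", "R4"),
        ]
        assert partition.modularity == pytest.approx(0.4231, abs=1e-4)

    def test_twin_cliques_split_is_global_optimum(self, twin_cliques):
        # exhaustive search over all 4140 partitions of the 8 nodes
        undirected = {frozenset(e) for e in twin_cliques.edges}
        best_q, best_blocks = best_modularity_partition(
            sorted(twin_cliques.nodes), undirected
        )
        partition = louvain(twin_cliques, seed=0)
        assert blocks(partition) == best_blocks
        assert partition.modularity == pytest.approx(best_q, abs=1e-12)

    def test_disconnected_paths_each_their_own_module(self):
        reactions = [
            ElementaryReaction(f"r{i}", frozenset([a]), frozenset([b]), "platelet")
            for i, (a, b) in enumerate([("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")])
        ]
        net = build_network(reactions)
        partition = louvain(net, seed=0)
        assert blocks(partition) == [("A", "B", "C"), ("X", "Y", "Z")]
        undirected = {frozenset(e) for e in net.edges}
        best_q, best_blocks = best_modularity_partition(sorted(net.nodes), undirected)
        assert blocks(partition) == best_blocks

    def test_single_edge_one_module(self):
        net = ProteinNetwork.from_edges([("A", "B")])
        partition = louvain(net, seed=0)
        assert partition.n_modules == 1 and partition.module_sizes == {1: 2}

    def test_returned_q_matches_rescoring(self, twin_cliques):
        partition = louvain(twin_cliques, seed=5)
        assert partition.modularity == pytest.approx(
            modularity_score(twin_cliques, partition.assignment), abs=1e-12
        )

    def test_q_never_below_trivial_partition_on_connected_graphs(self, cycle10):
        for seed in range(5):
            assert louvain(cycle10, seed=seed).modularity >= -1e-12

    def test_module_ids_ordered_by_decreasing_size(self):
        # 4-clique plus a separate edge: module 1 must be the clique
        edges = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"),
                 ("X", "Y")]
        net = ProteinNetwork.from_edges(edges)
        partition = louvain(net, seed=0)
        assert list(partition.module_sizes.values()) == sorted(
            partition.module_sizes.values(), reverse=True
        )
        assert set(partition.members(1)) == {"A", "B", "C", "D"}


class TestModularHubs:
    def test_single_node_module(self):
        net = ProteinNetwork.from_edges([("A", "B")], extra_nodes=["Z"])
        hubs = modular_hubs(net, {"A": 1, "B": 1, "Z": 2}, top_k=4)
        assert hubs[2] == ["Z"]

    def test_tie_broken_lexicographically(self):
        # X has degree 3; Y and Z tie at lower degree -> Y wins the tie
        edges = [("X", "Y"), ("X", "Z"), ("X", "W"), ("Y", "Z")]
        net = ProteinNetwork.from_edges(edges)
        hubs = modular_hubs(net, {n: 1 for n in net.nodes}, top_k=2)
        assert hubs[1] == ["X", "Y"]

    def test_star_hub_tops_its_module(self, star5_out):
        partition = louvain(star5_out, seed=0)
        assert modular_hubs(star5_out, partition, top_k=1)[1] == ["H"]

    def test_degree_taken_on_full_network(self, twin_cliques):
        partition = louvain(twin_cliques, seed=0)
        hubs = modular_hubs(twin_cliques, partition, top_k=1)
        # bridge endpoints L4 and R1 have degree 4, others 3
        assert sorted(v[0] for v in hubs.values()) == ["L4", "R1"]
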