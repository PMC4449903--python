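"""Node centralities, network summary, hubs, and group comparison.

Three centralities are computed on the protein network:

``degree``
    Number of distinct partners a node is connected to by an arrow in
    either direction; a bidirectional pair counts once.
``betweenness``
    Sum over ordered node pairs (u, w), u != v != w, of the fraction of
    shortest u->w paths passing through v (unweighted; pairs with no
    connecting path contribute 0).  Raw, unnormalised counts.
``closeness``
    Mean shortest-path distance from v to the nodes it can reach.
    Note the orientation: LOWER values mean a more central node, and a
    node that reaches nothing (e.g. an isolated node) gets the sentinel
    value 0.

``direction_mode`` selects whether paths follow the reaction stream
(``"directed"``, the default) or ignore it (``"undirected"``).  Degree
is direction-free by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import networkx as nx

from .errors import SummaryError
from .network_builder import ProteinNetwork, multifunctional_nodes, weak_components

DirectionMode = Literal["directed", "undirected"]


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    degree: int
    betweenness: float
    closeness: float
    functions: frozenset[str]
    is_multifunctional: bool
    is_hub: bool


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float  # n_edges / n_nodes
    average_shortest_path: float  # mean distance over ordered reachable pairs
    n_components: int


@dataclass(frozen=True)
class GroupComparison:
    """Mean degree/betweenness/closeness for multifunctional vs not.

    ``group_means`` maps group name -> {"degree": .., "betweenness": ..,
    "closeness": ..}; an empty group is reported in ``empty_groups``
    rather than raising.
    """

    group_means: dict[str, dict[str, float]]
    group_sizes: dict[str, int]
    empty_groups: tuple[str, ...]


def _paths_graph(network: ProteinNetwork, direction_mode: DirectionMode):
    if direction_mode == "directed":
        return network.to_digraph()
    if direction_mode == "undirected":
        return network.to_undirected_graph()
    raise ValueError(f"direction_mode must be 'directed' or 'undirected', got {direction_mode!r}")


def degree_all(network: ProteinNetwork) -> dict[str, int]:
    """Number of distinct neighbours, arrow direction ignored."""
    g = network.to_undirected_graph()
    return {n: int(d) for n, d in g.degree()}


def betweenness_all(
    network: ProteinNetwork, direction_mode: DirectionMode = "directed"
) -> dict[str, float]:
    """Raw shortest-path betweenness over ordered node pairs."""
    g = _paths_graph(network, direction_mode)
    bc = nx.betweenness_centrality(g, normalized=False)
    if direction_mode == "undirected":
        # networkx reports unordered-pair counts on undirected graphs;
        # the ordered-pair convention doubles them
        bc = {n: 2.0 * v for n, v in bc.items()}
    return {n: float(v) for n, v in bc.items()}


def closeness_all(
    network: ProteinNetwork, direction_mode: DirectionMode = "directed"
) -> dict[str, float]:
    """Mean distance to reachable nodes; 0 when nothing is reachable."""
    g = _paths_graph(network, direction_mode)
    out: dict[str, float] = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        dist.pop(v, None)
        out[v] = sum(dist.values()) / len(dist) if dist else 0.0
    return out


def summarize(network: ProteinNetwork) -> NetworkSummary:
    """Whole-network summary statistics.

    ``average_degree`` is the edge-to-node ratio ``n_edges / n_nodes``;
    ``average_shortest_path`` is the mean directed distance over ordered
    reachable pairs u != v.
    """
    if network.n_nodes == 0:
        raise SummaryError("cannot summarize an empty network")
    g = network.to_digraph()
    total, pairs = 0, 0
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        dist.pop(v, None)
        total += sum(dist.values())
        pairs += len(dist)
    return NetworkSummary(
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        average_degree=network.n_edges / network.n_nodes,
        average_shortest_path=total / pairs if pairs else 0.0,
        n_components=len(weak_components(network)),
    )


def centrality_table(
    network: ProteinNetwork,
    direction_mode: DirectionMode = "directed",
    hub_threshold: int = 10,
) -> list[CentralityRecord]:
    """Per-node centrality records, ranked by decreasing degree.

    Ties are broken lexicographically by node id.  ``is_hub`` marks
    degree >= ``hub_threshold``; ``is_multifunctional`` marks nodes
    annotated with two or more subsystems.
    """
    deg = degree_all(network)
    bet = betweenness_all(network, direction_mode)
    clo = closeness_all(network, direction_mode)
    multi = multifunctional_nodes(network)
    records = [
        CentralityRecord(
            node=n,
            degree=deg[n],
            betweenness=bet[n],
            closeness=clo[n],
            functions=network.node_functions.get(n, frozenset()),
            is_multifunctional=n in multi,
            is_hub=deg[n] >= hub_threshold,
        )
        for n in network.nodes
    ]
    return sorted(records, key=lambda r: (-r.degree, r.node))


def extract_hubs(
    records: Iterable[CentralityRecord], threshold: int = 10
) -> list[CentralityRecord]:
    """Records with degree >= threshold, by decreasing degree then node id."""
    hubs = [r for r in records if r.degree >= threshold]
    return sorted(hubs, key=lambda r: (-r.degree, r.node))


_CENTRALITIES = ("degree", "betweenness", "closeness")


def compare_groups(records: Iterable[CentralityRecord]) -> GroupComparison:
    """Mean centralities of multifunctional vs nonmultifunctional nodes."""
    groups: dict[str, list[CentralityRecord]] = {
        "multifunctional": [],
        "nonmultifunctional": [],
    }
    for r in records:
        groups["multifunctional" if r.is_multifunctional else "nonmultifunctional"].append(r)
    means: dict[str, dict[str, float]] = {}
    empty: list[str] = []
    for name, members in groups.items():
        if not members:
            empty.append(name)
            means[name] = {c: float("nan") for c in _CENTRALITIES}
            continue
        means[name] = {
            c: sum(getattr(r, c) for r in members) / len(members) for c in _CENTRALITIES
        }
    return GroupComparison(
        group_means=means,
        group_sizes={name: len(members) for name, members in groups.items()},
        empty_groups=tuple(empty),
    )
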