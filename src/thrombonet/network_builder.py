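"""Directed protein network construction from elementary reactions.

An *elementary reaction* is a pathway reaction reduced to one reactant
group and one product group of proteins (small molecules discarded),
labelled by the functional subsystem it belongs to.  Multi-protein
complexes are split into their member proteins and every reactant
protein is connected to every *different* product protein with a
directed edge following the reaction stream; self-connections are never
created.  A protein pair linked in both directions forms a
*bidirectional pair*, the signature of proteins that act together in a
complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import ReactionParseError

#: The three functional subsystems of the thrombosis model:
#: platelet activation/signalling/aggregation, the coagulation
#: (clotting) cascade, and fibrin clot dissolution.
SUBSYSTEMS: tuple[str, str, str] = ("platelet", "coagulation", "dissolution")


@dataclass(frozen=True)
class ElementaryReaction:
    """One reactant protein group, one product protein group, a subsystem.

    Parameters
    ----------
    reaction_id:
        Unique identifier of the reaction record.
    reactants, products:
        Non-empty sets of protein identifiers.  Identifiers are
        case-sensitive and whitespace-trimmed.
    subsystem:
        One of :data:`SUBSYSTEMS`.
    """

    reaction_id: str
    reactants: frozenset[str]
    products: frozenset[str]
    subsystem: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", frozenset(self.reactants))
        object.__setattr__(self, "products", frozenset(self.products))
        self.validate()

    def validate(self) -> None:
        if not self.reactants:
            raise ReactionParseError(self.reaction_id, "empty reactant set")
        if not self.products:
            raise ReactionParseError(self.reaction_id, "empty product set")
        for group in (self.reactants, self.products):
            for p in group:
                if not isinstance(p, str) or not p.strip():
                    raise ReactionParseError(
                        self.reaction_id, f"invalid protein identifier {p!r}"
                    )
        if self.subsystem not in SUBSYSTEMS:
            raise ReactionParseError(
                self.reaction_id,
                f"unknown subsystem {self.subsystem!r}; expected one of {SUBSYSTEMS}",
            )


@dataclass(frozen=True)
class ProteinNetwork:
    """Simple directed graph of proteins with subsystem annotations.

    ``edges`` is a set of ordered pairs ``(u, v)`` with ``u != v`` —
    duplicates implied by several reactions are stored once.
    ``node_functions`` maps each node to the (possibly empty, for
    networks imported without annotations) set of subsystems of the
    reactions it participates in.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    node_functions: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        funcs = {n: frozenset(self.node_functions.get(n, ())) for n in self.nodes}
        object.__setattr__(self, "node_functions", funcs)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-connection {u!r}->{v!r} is not allowed")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({u!r}, {v!r})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def bidirectional_pairs(self) -> frozenset[frozenset[str]]:
        """Unordered pairs {u, v} with both (u, v) and (v, u) present."""
        return frozenset(
            frozenset((u, v)) for (u, v) in self.edges if (v, u) in self.edges
        )

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def to_undirected_graph(self) -> nx.Graph:
        """Undirected simple projection (a bidirectional pair is one edge)."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        node_functions: Mapping[str, Iterable[str]] | None = None,
        extra_nodes: Iterable[str] = (),
    ) -> "ProteinNetwork":
        edge_set = frozenset(tuple(e) for e in edges)
        nodes = {u for e in edge_set for u in e} | set(extra_nodes)
        funcs = {
            n: frozenset(fs) for n, fs in (node_functions or {}).items() if n in nodes
        }
        return cls(frozenset(nodes), edge_set, funcs)


def build_network(reactions: Iterable[ElementaryReaction]) -> ProteinNetwork:
    """Split complexes and reconnect each reactant to each different product.

    For every reaction, a directed edge ``r -> p`` is added for each
    reactant protein ``r`` and product protein ``p`` with ``r != p``.
    Edges implied by several reactions are stored once.  A protein's
    functions are the union of the subsystems of the reactions it
    participates in, so a protein active in two subsystems is annotated
    with both (a *multifunctional* protein).

    An empty reaction list yields an empty network.
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    functions: dict[str, set[str]] = {}
    for rxn in reactions:
        rxn.validate()
        members = rxn.reactants | rxn.products
        nodes.update(members)
        for p in members:
            functions.setdefault(p, set()).add(rxn.subsystem)
        for r in rxn.reactants:
            for p in rxn.products:
                if r != p:
                    edges.add((r, p))
    return ProteinNetwork(
        frozenset(nodes),
        frozenset(edges),
        {n: frozenset(fs) for n, fs in functions.items()},
    )


def multifunctional_nodes(network: ProteinNetwork) -> set[str]:
    """Nodes annotated with two or more subsystems."""
    return {n for n, fs in network.node_functions.items() if len(fs) >= 2}


def weak_components(network: ProteinNetwork) -> list[set[str]]:
    """Weakly connected components, direction ignored.

    Sorted by decreasing size, ties broken by the lexicographically
    smallest member.
    """
    comps = [set(c) for c in nx.weakly_connected_components(network.to_digraph())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
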