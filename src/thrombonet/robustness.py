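"""Robustness of the network under random failure and targeted attack.

Following the classic error-and-attack-tolerance framework, a fraction
f of nodes is removed either at random (*failure*), in decreasing
degree order (*hub attack*), or in decreasing betweenness order
(*bridge attack*), and two indicators are tracked:

``S``
    Size of the largest remaining weakly connected component divided
    by the ORIGINAL node count.
``<s>``
    Mean size of the remaining components excluding the single largest
    one; isolated single nodes count as size-1 components.  0 when at
    most one component remains.

Attack rankings are computed once on the intact network (static
attack) unless ``adaptive`` is set, in which case the ranking is
recomputed after every single removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .centrality import betweenness_all, degree_all
from .errors import ConfigurationError
from .network_builder import ProteinNetwork

RemovalMode = Literal["random", "hub", "bridge"]

DEFAULT_REPLICATES = 100
DEFAULT_FMAX = 0.10


@dataclass(frozen=True)
class RemovalPlan:
    """What to remove, how fast, and how often.

    ``f_grid`` defaults to 0 .. 0.10 in steps of 1/N (one node per
    step) when left unset.  ``replicates`` only matters for the random
    mode; deterministic modes always run once.
    """

    mode: RemovalMode
    f_grid: tuple[float, ...] | None = None
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    adaptive: bool = False

    def validate(self) -> None:
        if self.mode not in ("random", "hub", "bridge"):
            raise ConfigurationError(f"unknown removal mode {self.mode!r}")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be a positive integer")
        if self.f_grid is not None:
            fg = tuple(self.f_grid)
            if any(b <= a for a, b in zip(fg, fg[1:])):
                raise ConfigurationError("f_grid must be strictly increasing")
            if fg and (fg[0] < 0 or fg[-1] > 1):
                raise ConfigurationError("f_grid must lie within [0, 1]")


@dataclass(frozen=True)
class RobustnessCurve:
    mode: RemovalMode
    f_values: tuple[float, ...]
    S_values: tuple[float, ...]
    s_avg_values: tuple[float, ...]
    replicate_count: int = 1


def default_f_grid(n_nodes: int, fmax: float = DEFAULT_FMAX) -> tuple[float, ...]:
    """Per-node-resolution grid 0, 1/N, 2/N, ... up to fmax."""
    steps = int(math.floor(fmax * n_nodes + 1e-9))
    return tuple(k / n_nodes for k in range(steps + 1))


def _fragment_stats(g: nx.Graph, removed: Sequence[str], n_total: int):
    """(S, <s>) after deleting ``removed`` from the undirected projection."""
    h = g.copy()
    h.remove_nodes_from(removed)
    sizes = sorted((len(c) for c in nx.connected_components(h)), reverse=True)
    if not sizes:
        return 0.0, 0.0
    S = sizes[0] / n_total
    rest = sizes[1:]
    s_avg = sum(rest) / len(rest) if rest else 0.0
    return S, s_avg


def _static_order(network: ProteinNetwork, mode: RemovalMode) -> list[str]:
    if mode == "hub":
        score = degree_all(network)
    else:  # bridge
        score = betweenness_all(network, "directed")
    return sorted(network.nodes, key=lambda n: (-score[n], n))


def _adaptive_removals(network: ProteinNetwork, mode: RemovalMode, k_max: int) -> list[str]:
    """Remove one node at a time, re-ranking on the shrunken network."""
    removed: list[str] = []
    current = network
    for _ in range(min(k_max, network.n_nodes)):
        target = _static_order(current, mode)[0]
        removed.append(target)
        keep = current.nodes - {target}
        current = ProteinNetwork(
            frozenset(keep),
            frozenset(e for e in current.edges if e[0] in keep and e[1] in keep),
            {n: current.node_functions[n] for n in keep},
        )
    return removed


def simulate_removal(network: ProteinNetwork, plan: RemovalPlan) -> RobustnessCurve:
    """Fragmentation curve S(f), <s>(f) under the plan's removal mode.

    At each grid fraction f the first ceil(f*N) nodes of the removal
    order are deleted.  Random-mode curves are averaged over
    ``plan.replicates`` seeded permutations; hub and bridge attacks are
    deterministic (ties broken lexicographically) and run once.
    """
    plan.validate()
    n = network.n_nodes
    if n < 2:
        raise ConfigurationError("robustness simulation needs >= 2 nodes")
    f_grid = tuple(plan.f_grid) if plan.f_grid is not None else default_f_grid(n)
    g = network.to_undirected_graph()
    counts = [min(math.ceil(f * n - 1e-12), n) for f in f_grid]

    if plan.mode == "random":
        rng = np.random.default_rng(plan.seed)
        all_nodes = sorted(network.nodes)
        S_acc = np.zeros(len(f_grid))
        s_acc = np.zeros(len(f_grid))
        for _ in range(plan.replicates):
            order = [all_nodes[i] for i in rng.permutation(n)]
            for j, k in enumerate(counts):
                S, s_avg = _fragment_stats(g, order[:k], n)
                S_acc[j] += S
                s_acc[j] += s_avg
        return RobustnessCurve(
            mode="random",
            f_values=f_grid,
            S_values=tuple(S_acc / plan.replicates),
            s_avg_values=tuple(s_acc / plan.replicates),
            replicate_count=plan.replicates,
        )

    if plan.adaptive:
        order = _adaptive_removals(network, plan.mode, max(counts))
    else:
        order = _static_order(network, plan.mode)
    S_vals, s_vals = [], []
    for k in counts:
        S, s_avg = _fragment_stats(g, order[:k], n)
        S_vals.append(S)
        s_vals.append(s_avg)
    return RobustnessCurve(
        mode=plan.mode,
        f_values=f_grid,
        S_values=tuple(S_vals),
        s_avg_values=tuple(s_vals),
        replicate_count=1,
    )


def fragmentation_threshold(
    curve: RobustnessCurve, S_cut: float = 0.2
) -> float | None:
    """Smallest grid fraction with S(f) <= S_cut, or None if never reached."""
    for f, S in zip(curve.f_values, curve.S_values):
        if S <= S_cut:
            return f
    return None
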