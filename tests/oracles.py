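"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive and self-contained: shortest
paths are found by enumerating ALL simple paths in order of increasing
length, partitions by full set-partition enumeration, and power-law
samples by an inverse-CDF lookup.  None of it shares code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def enumerate_shortest_paths(edges: set[tuple], nodes: list, u, w):
    """All shortest u->w paths by iterative-deepening enumeration.

    Returns (distance, list_of_paths); (None, []) when unreachable.
    """
    if u == w:
        return 0, [(u,)]
    others = [x for x in nodes if x != u]
    for length in range(1, len(nodes)):
        found = []
        stack = [(u,)]
        while stack:
            path = stack.pop()
            if len(path) - 1 == length:
                if path[-1] == w:
                    found.append(path)
                continue
            for x in others:
                if x in path or (path[-1], x) not in edges:
                    continue
                if x == w and len(path) != length:  # w only at final hop
                    continue
                stack.append(path + (x,))
        if found:
            return length, found
    return None, []


def brute_betweenness(nodes: list, edges: set[tuple]) -> dict:
    """Raw betweenness over ordered pairs via full path enumeration."""
    bc = {v: Fraction(0) for v in nodes}
    for u, w in itertools.permutations(nodes, 2):
        _, paths = enumerate_shortest_paths(edges, nodes, u, w)
        if not paths:
            continue
        sigma = len(paths)
        through: dict = {}
        for path in paths:
            for v in path[1:-1]:
                through[v] = through.get(v, 0) + 1
        for v, cnt in through.items():
            bc[v] += Fraction(cnt, sigma)
    return {v: float(x) for v, x in bc.items()}


def brute_closeness(nodes: list, edges: set[tuple]) -> dict:
    """Mean distance to reachable nodes; 0 when nothing is reachable."""
    out = {}
    for v in nodes:
        dists = []
        for u in nodes:
            if u == v:
                continue
            d, paths = enumerate_shortest_paths(edges, nodes, v, u)
            if paths:
                dists.append(d)
        out[v] = sum(dists) / len(dists) if dists else 0.0
    return out


def symmetrize(edges: set[tuple]) -> set[tuple]:
    return edges | {(v, u) for (u, v) in edges}


# ---------------------------------------------------------------------------
# Digraph enumeration up to isomorphism


def digraph_isomorphism_representatives(n: int) -> list[set[tuple[int, int]]]:
    """One labeled representative per isomorphism class of n-node digraphs.

    Each digraph on nodes 0..n-1 is a bitmask over the n(n-1) ordered
    pairs; the canonical form is the minimum mask over all node
    permutations, computed for every mask at once with vectorised bit
    permutations.
    """
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    index = {p: b for b, p in enumerate(pairs)}
    m = len(pairs)
    masks = np.arange(1 << m, dtype=np.uint32)
    canon = masks.copy()
    for perm in itertools.permutations(range(n)):
        target = [index[(perm[i], perm[j])] for (i, j) in pairs]
        permuted = np.zeros_like(masks)
        for b in range(m):
            permuted |= ((masks >> np.uint32(b)) & np.uint32(1)) << np.uint32(target[b])
        np.minimum(canon, permuted, out=canon)
    reps = np.nonzero(canon == masks)[0]
    return [
        {pairs[b] for b in range(m) if mask >> b & 1} for mask in reps.tolist()
    ]


def random_digraph(n: int, p: float, rng: np.random.Generator) -> set[tuple[int, int]]:
    return {
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    }


# ---------------------------------------------------------------------------
# Exhaustive partition search


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_modularity_partition(nodes: list, undirected_edges: set[frozenset]):
    """Arg-max modularity over ALL partitions, by direct formula."""
    m = len(undirected_edges)
    deg = {v: sum(1 for e in undirected_edges if v in e) for v in nodes}
    best_q, best_p = -2.0, None
    for part in all_partitions(nodes):
        q = 0.0
        for block in part:
            bset = set(block)
            e_c = sum(1 for e in undirected_edges if e <= bset)
            d_c = sum(deg[v] for v in block)
            q += e_c / m - (d_c / (2 * m)) ** 2
        if q > best_q + 1e-12:
            best_q, best_p = q, part
    return best_q, sorted(tuple(sorted(b)) for b in best_p)


# ---------------------------------------------------------------------------
# Discrete power-law sampling (independent inverse-CDF implementation)


def sample_power_law(
    n: int, gamma: float, k_max: int, rng: np.random.Generator
) -> np.ndarray:
    """n draws from p(k) proportional to k^-gamma on k = 1..k_max."""
    k = np.arange(1, k_max + 1, dtype=float)
    w = k**-gamma
    cdf = np.cumsum(w) / w.sum()
    return 1 + np.searchsorted(cdf, rng.random(n))
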