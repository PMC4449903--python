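"""Synthetic Reactome-like elementary-reaction sets and fixture networks.

The generator emulates the structure of a curated reaction export for a
three-subsystem disease network: disjoint protein pools per subsystem,
a small planted set of *multifunctional* proteins that participate in
two subsystems, reactions whose reactant/product sides may be
multi-protein complexes, and preferential reuse of already-active
proteins so that the resulting protein network has a heavy-tailed
degree distribution.

All sampling is driven by a single :class:`numpy.random.Generator`
seeded from the config; identical configs produce byte-identical
serialized reaction sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FixtureLookupError
from .network_builder import SUBSYSTEMS, ElementaryReaction, ProteinNetwork

#: Default distribution of complex (group) sizes for each reaction side.
#: Most elementary reactions involve small complexes; singleton sides
#: dominate.
DEFAULT_COMPLEX_SIZE_PROBS: dict[int, float] = {1: 0.50, 2: 0.30, 3: 0.15, 4: 0.05}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic reaction-set generator.

    Defaults mirror the published thrombosis network's scale: ~150
    participating proteins and ~400 directed relations after complex
    splitting, three subsystems with platelet signalling the largest,
    four planted multifunctional proteins, and attachment strong
    enough for a heavy-tailed degree distribution.
    """

    n_proteins: int = 150
    n_reactions: int = 200
    subsystem_weights: tuple[float, float, float] = (0.60, 0.25, 0.15)
    overlap_count: int = 4
    complex_size_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEX_SIZE_PROBS)
    )
    preferential_attachment_strength: float = 1.0
    chain_probability: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be a positive integer")
        if self.n_reactions < 0:
            raise ConfigurationError("n_reactions must be non-negative")
        if len(self.subsystem_weights) != 3 or any(
            w < 0 for w in self.subsystem_weights
        ):
            raise ConfigurationError(
                "subsystem_weights must be three non-negative fractions"
            )
        if abs(sum(self.subsystem_weights) - 1.0) > 1e-9:
            raise ConfigurationError("subsystem_weights must sum to 1 within 1e-9")
        if self.overlap_count < 0:
            raise ConfigurationError("overlap_count must be non-negative")
        if self.overlap_count >= self.n_proteins:
            raise ConfigurationError("overlap_count must be < n_proteins")
        if not self.complex_size_probs or any(
            (k < 1 or p < 0) for k, p in self.complex_size_probs.items()
        ):
            raise ConfigurationError(
                "complex_size_probs requires sizes >= 1 and non-negative probabilities"
            )
        if abs(sum(self.complex_size_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("complex_size_probs values must sum to 1 within 1e-9")
        if self.preferential_attachment_strength < 0:
            raise ConfigurationError(
                "preferential_attachment_strength must be non-negative"
            )
        if not 0.0 <= self.chain_probability < 1.0:
            raise ConfigurationError("chain_probability must be in [0, 1)")


def _partition_pools(config: GeneratorConfig, rng: np.random.Generator):
    """Assign each protein a home subsystem; pick overlap proteins.

    Pool sizes follow subsystem_weights by largest remainder.  Each of
    the ``overlap_count`` overlap proteins additionally receives a
    secondary subsystem different from its home, making it eligible for
    reactions of both.
    """
    proteins = [f"P{i:03d}" for i in range(1, config.n_proteins + 1)]
    weights = np.asarray(config.subsystem_weights, dtype=float)
    raw = weights * config.n_proteins
    sizes = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts
    for idx in np.argsort(-(raw - sizes))[: config.n_proteins - sizes.sum()]:
        sizes[idx] += 1
    home: dict[str, str] = {}
    pos = 0
    for sub, size in zip(SUBSYSTEMS, sizes):
        for p in proteins[pos : pos + size]:
            home[p] = sub
        pos += size

    # overlap proteins must come from non-empty pools and get a distinct
    # secondary subsystem (weighted by the remaining subsystem weights)
    eligible_for_overlap = [p for p in proteins if weights[SUBSYSTEMS.index(home[p])] > 0]
    overlap = sorted(
        str(p)
        for p in rng.choice(eligible_for_overlap, size=config.overlap_count, replace=False)
    )
    secondary: dict[str, str] = {}
    for p in overlap:
        others = [s for s in SUBSYSTEMS if s != home[p]]
        w = np.array([max(weights[SUBSYSTEMS.index(s)], 1e-12) for s in others])
        secondary[p] = str(rng.choice(others, p=w / w.sum()))
    return proteins, home, overlap, secondary


#: Exponent scale translating ``preferential_attachment_strength`` into
#: the anchor/partner sampling weights (1+usage)^(+/- _BIAS * strength).
_BIAS = 2.5


def _sample_group(
    pool: list[str],
    size: int,
    usage: dict[str, int],
    exponent: float,
    rng: np.random.Generator,
) -> set[str]:
    """Sample ``size`` distinct proteins with usage-power weighting.

    A positive exponent prefers heavily-used proteins (hub anchors), a
    negative one prefers fresh proteins (new substrates).
    """
    size = min(size, len(pool))
    w = np.array([(1.0 + usage[p]) ** exponent for p in pool])
    chosen = rng.choice(pool, size=size, replace=False, p=w / w.sum())
    return {str(c) for c in chosen}


def generate_reactions(config: GeneratorConfig) -> list[ElementaryReaction]:
    """Generate a synthetic elementary-reaction set.

    Each reaction pairs an *anchor* — a single recurring protein chosen
    preferentially by prior usage, playing the role of the hub enzymes
    and named complex nodes that appear in many pathway reactions —
    with a *partner* group of 1-4 mostly fresh proteins whose size
    follows ``complex_size_probs``; which side is reactant and which is
    product is random.  With probability ``chain_probability`` a
    reaction instead continues a cascade, reusing the previous
    reaction's product group (same subsystem) as its reactant group.
    The result is a hub-and-spoke network with pendant reaction chains:
    heavy-tailed degrees and strong fragility to hub removal, the
    structural signature of curated pathway networks.

    Exactly ``overlap_count`` proteins end up participating in
    reactions of two subsystems (the planted multifunctional set);
    every other protein that appears stays inside its home subsystem.
    """
    config.validate()
    if config.n_reactions == 0:
        return []
    rng = np.random.default_rng(config.seed)
    proteins, home, overlap, secondary = _partition_pools(config, rng)

    pools: dict[str, list[str]] = {
        sub: sorted(
            [p for p in proteins if home[p] == sub]
            + [p for p in overlap if secondary[p] == sub]
        )
        for sub in SUBSYSTEMS
    }
    weights = np.asarray(config.subsystem_weights, dtype=float)
    subsystem_draws = [
        SUBSYSTEMS[i]
        for i in rng.choice(3, size=config.n_reactions, p=weights / weights.sum())
    ]
    # every subsystem hosting an overlap protein needs at least one
    # reaction, otherwise the plant cannot be realised
    needed = sorted({home[p] for p in overlap} | {secondary[p] for p in overlap})
    spare = config.n_reactions - 1
    for sub in needed:
        if sub not in subsystem_draws:
            subsystem_draws[spare] = sub
            spare -= 1

    sizes = sorted(config.complex_size_probs)
    size_probs = np.array([config.complex_size_probs[s] for s in sizes])
    size_probs = size_probs / size_probs.sum()
    usage: dict[str, int] = {p: 0 for p in proteins}
    up = _BIAS * config.preferential_attachment_strength

    reactants_list: list[set[str]] = []
    products_list: list[set[str]] = []
    last_products: dict[str, list[str]] = {}
    prev_sub: str | None = None
    for sub in subsystem_draws:
        pool = pools[sub]
        p_size = int(rng.choice(sizes, p=size_probs))
        chained = (
            prev_sub == sub
            and sub in last_products
            and rng.random() < config.chain_probability
        )
        if chained:
            reactants = set(last_products[sub])
            products = _sample_group(pool, p_size, usage, -up, rng)
        else:
            reactants = _sample_group(pool, 1, usage, up, rng)
            products = _sample_group(pool, p_size, usage, -up, rng)
            if rng.random() < 0.5:
                reactants, products = products, reactants
        for p in sorted(reactants | products):
            usage[p] += 1
        last_products[sub] = sorted(products)
        prev_sub = sub
        reactants_list.append(reactants)
        products_list.append(products)

    # plant: force each overlap protein into >=1 reaction of each of its
    # two subsystems (inserted as an extra reactant where missing)
    seen: dict[str, set[str]] = {p: set() for p in proteins}
    for sub, r, pr in zip(subsystem_draws, reactants_list, products_list):
        for p in r | pr:
            seen[p].add(sub)
    for p in overlap:
        for sub in (home[p], secondary[p]):
            if sub not in seen[p]:
                candidates = [i for i, s in enumerate(subsystem_draws) if s == sub]
                i = int(rng.choice(candidates))
                reactants_list[i].add(p)
                seen[p].add(sub)

    width = len(str(config.n_reactions))
    return [
        ElementaryReaction(
            reaction_id=f"R{i + 1:0{width}d}",
            reactants=frozenset(r),
            products=frozenset(pr),
            subsystem=sub,
        )
        for i, (sub, r, pr) in enumerate(
            zip(subsystem_draws, reactants_list, products_list)
        )
    ]


def _bidirectional(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [e for (u, v) in pairs for e in ((u, v), (v, u))]


def _fixture_specs() -> dict[str, ProteinNetwork]:
    plat = "platelet"
    cl4 = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
    twin = (
        [(f"L{a}", f"L{b}") for a, b in [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]]
        + [(f"R{a}", f"R{b}") for a, b in [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]]
        + [("L4", "R1")]
    )
    cyc = [(f"N{i}", f"N{(i + 1) % 10}") for i in range(10)]
    specs = {
        "path3": ProteinNetwork.from_edges([("A", "B"), ("B", "C")]),
        "path4": ProteinNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")]),
        "star5_out": ProteinNetwork.from_edges(
            [("H", "L1"), ("H", "L2"), ("H", "L3"), ("H", "L4")]
        ),
        "cycle10": ProteinNetwork.from_edges(_bidirectional(cyc)),
        "clique4": ProteinNetwork.from_edges(_bidirectional(cl4)),
        "twin_cliques": ProteinNetwork.from_edges(_bidirectional(twin)),
        "bidir_pair": ProteinNetwork.from_edges([("A", "B"), ("B", "A")]),
        "isolated_plus_edge": ProteinNetwork.from_edges(
            [("A", "B")], extra_nodes=["Z"]
        ),
    }
    return {
        name: ProteinNetwork(
            net.nodes, net.edges, {n: frozenset((plat,)) for n in net.nodes}
        )
        for name, net in specs.items()
    }


FIXTURE_NAMES: tuple[str, ...] = tuple(sorted(_fixture_specs()))


def fixture_network(name: str) -> ProteinNetwork:
    """Return a small hand-specified network used as a test oracle.

    Available fixtures
    ------------------
    path3
        A->B->C.
    path4
        A->B->C->D.
    star5_out
        Hub H with edges to four leaves.
    cycle10
        Bidirectional 10-cycle.
    clique4
        Four mutually connected nodes (all edges bidirectional).
    twin_cliques
        Two bidirectional 4-cliques joined by one bidirectional bridge
        (8 nodes, 13 undirected adjacencies).
    bidir_pair
        A<->B.
    isolated_plus_edge
        Edge A->B plus isolated node Z.
    """
    specs = _fixture_specs()
    if name not in specs:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {', '.join(sorted(specs))}"
        )
    return specs[name]
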