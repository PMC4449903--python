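# Methods

This note records the modelling conventions, parameter choices, and
numerical decisions behind thrombonet, and what the synthetic data can
and cannot say about real pathway networks.

## Network construction

An elementary reaction is one reactant protein group, one product
protein group, and a subsystem label (platelet signalling, coagulation
cascade, or clot dissolution). Complex splitting connects every
reactant protein to every *different* product protein with a directed
edge; self-connections are never created. Conventions:

- **Deduplication.** A relation implied by several reactions is stored
  once; the edge count is therefore set-like.
- **Node inclusion.** Every protein mentioned in any reaction becomes
  a node, whether or not it ends up with edges.
- **Annotations.** A protein's functions are the union of the
  subsystems of its reactions; a protein with ≥ 2 functions is
  *multifunctional*.
- **Identifiers** are case-sensitive and whitespace-trimmed.
- **Components** are weakly connected (direction ignored), the
  convention used throughout robustness analysis.

## Centralities

Degree counts distinct partners regardless of arrow direction, so a
bidirectional pair contributes one. Betweenness sums σ_{u,w}(v)/σ_{u,w}
over *ordered* node pairs on unweighted shortest paths; pairs with no
connecting path contribute zero. Closeness is reported as the raw mean
distance to reachable nodes — *lower* is more central — with a 0
sentinel for nodes that reach nothing. This orientation matches how
the quantity is defined from mean shortest-path length rather than its
reciprocal; consumers ranking by closeness should sort ascending and
treat 0 as "isolated", not "most central".

`direction_mode` selects directed (default — edges encode the reaction
stream) or undirected paths for betweenness/closeness; both are
exposed because published tables do not always state which convention
produced them. In undirected mode the betweenness of networkx (which
counts unordered pairs) is doubled to keep the ordered-pair convention
consistent across modes.

The network summary defines average degree as `n_edges / n_nodes`
(the edge-to-node ratio used in pathway-network reports, ≈ 2.78 for a
149-node, 414-edge network) and average shortest path as the mean
directed distance over ordered reachable pairs.

Hub extraction uses degree ≥ threshold with a default of 10, the
inclusive reading consistent with published hub tables that list
degree-10 rows.

## Degree distribution fit

The default estimator is ordinary least squares of log p(k) on log k
over observed degrees k ≥ 1 with p(k) > 0, reporting γ = −slope, the
amplitude exp(intercept), the two-sided slope p-value, and r². This is
the regression-on-the-scatter procedure commonly applied to degree
histograms, and it needs at least three usable points. Degree-0 nodes
are excluded (log undefined) but still appear in the distribution;
k_min is fixed at 1 with no k_min search. Because OLS on raw p(k) is a
known-biased estimator, a discrete maximum-likelihood alternative
(zeta-normalised, k_min = 1, optimised by bounded scalar minimisation
on γ ∈ (1, 20]) is provided; its report carries the OLS log-log
diagnostics (p-value, r²) as descriptive measures of log-log linearity
since a likelihood exponent has no slope p-value of its own.

## Modules

Modularity Q = Σ_c [e_c/m − (d_c/2m)²] is evaluated on the undirected
simple projection with unit weights (a bidirectional pair is one
adjacency), the convention of the standard graph tools for this
analysis. Louvain community detection (seeded, resolution 1.0 by
default) runs on the same projection; the returned Q is always
re-scored from the final assignment with the direct formula. Module
ids are contiguous from 1 in decreasing size order so module 1 is
always the largest; modular hubs are each module's top-k members by
full-network degree (k = 4 by default, ties lexicographic). All
components receive module labels, including small disconnected ones.

## Robustness

S(f) is the size of the largest remaining weakly connected component
divided by the *original* node count after removing ⌈f·N⌉ nodes;
⟨s⟩(f) is the mean size of the remaining components excluding the
single largest, counting isolated nodes as size-1 components. Attack
rankings (degree for hub attack, directed betweenness for bridge
attack) are computed once on the intact network — a static attack,
matching a precomputed removal order — with an `adaptive` option that
re-ranks after every removal. Ties are broken lexicographically, so
deterministic modes are exactly reproducible. Random failure averages
S and ⟨s⟩ over seeded replicates (100 by default). The default grid is
0 to 0.10 in steps of 1/N — one node per grid point over the range
where scale-free networks show their characteristic attack
sensitivity. Removing every node is reported as S = 0, ⟨s⟩ = 0 rather
than an error.

## Synthetic data generator

The generator emulates the structure of a curated pathway export, not
any specific database's content. Each reaction pairs an **anchor** — a
single protein drawn with probability ∝ (1 + usage)^(2.5·strength),
playing the role of the recurring hub enzymes and named complex nodes
of real pathways — with a **partner group** of 1–4 proteins (sizes
from `complex_size_probs`) drawn with probability
∝ (1 + usage)^(−2.5·strength), i.e. biased toward fresh proteins, the
way new substrates enter a cascade. Which side is reactant is random.
With probability `chain_probability` (default 0.3) a reaction instead
continues a cascade by reusing the previous same-subsystem product
group as its reactant group. Together these produce the hub-and-spoke
topology with pendant reaction chains that characterises curated
disease pathways: heavy-tailed degrees, short-ish path lengths, and
strong fragility to hub removal alongside tolerance of random failure.

Subsystem pools are disjoint except for `overlap_count` planted
multifunctional proteins, each given one secondary subsystem and
guaranteed (by a deterministic fix-up pass) to appear in reactions of
both, so multifunctional detection recovers exactly the planted set.
Defaults — 150 proteins, 200 reactions, subsystem weights
(0.60, 0.25, 0.15) with platelet signalling the largest, 4 overlap
proteins, complex sizes {1: 0.50, 2: 0.30, 3: 0.15, 4: 0.05},
strength 1.0 — yield networks of ~150 nodes and ~320 directed edges
with fitted exponents around 1.0–1.2, the scale of the published
thrombosis network. All sampling flows from one seeded
`numpy.random.Generator`; identical configs give byte-identical
serialized output.

**What the generator does not emulate:** real protein identifiers,
stoichiometry, catalyst/regulator roles, small molecules,
database-specific complex-size statistics (none are published for the
reference network), or the biological clustering of real subsystems.
Tests passing on synthetic data demonstrate the correctness and the
qualitative topology-robustness relationships of the pipeline, not
quantitative agreement with any particular curated network — the
reference network's edge list was never deposited, so its exact
numbers are not reproducible from public information.

## Numerical choices and degenerate inputs

- Determinism everywhere: sets are sorted before sampling and
  serialization, so results do not depend on hash randomisation.
- One top-level pipeline seed is split into per-stage seeds with
  `numpy.random.SeedSequence` (values kept below 2^31).
- Empty reaction list → empty network (not an error); empty network →
  summary error; fits with < 3 usable points → fit error; a partial
  module assignment → error naming the missing nodes; unknown fixture
  names → error listing valid names.
- An empty comparison group is flagged (`empty_groups`) with NaN means
  rather than raising.
- Modularity of an edgeless network is defined as 0.
- Robustness requires ≥ 2 nodes; grid fractions at or above 1 report
  full removal.

## Problem sizes in the test suite

Exhaustive centrality checks run over one representative per
isomorphism class of all digraphs with ≤ 5 nodes (betweenness and
closeness are isomorphism-invariant, and label-invariance is
property-tested separately) plus 100 random digraphs with up to 12
nodes against an all-path enumeration oracle. Louvain recovery is
verified against exhaustive partition search at n ≤ 8. Power-law
recovery uses 10^5 draws per seed. Robustness comparisons use 20
synthetic 150-protein networks with 100 random-failure replicates.

## Known limitations

- OLS exponents on raw p(k) are biased for small samples; prefer
  `discrete_mle` when the exponent itself is the object of inference.
- Louvain is a greedy heuristic: only small planted cases are
  guaranteed (and verified) to reach the global modularity optimum.
- Static attack rankings understate damage relative to adaptive
  attacks on some topologies; both are available.
- The closeness variant used here is not comparable to reciprocal
  closeness values from other tools without transformation.
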