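# thrombonet

Topological analysis of reaction-derived protein networks, built around
the integrative human thrombosis network: platelet activation and
signalling, the coagulation cascade, and fibrin clot dissolution,
combined into one directed protein graph.

## Who this is for

Systems-biology and network-pharmacology researchers who want to turn
curated pathway reactions into a protein interaction network and ask
which proteins are promising intervention targets: hubs that
concentrate connections, bridges that carry shortest-path traffic,
multifunctional proteins that couple subsystems, and the nodes whose
removal fragments the network fastest.

## The model

**Construction.** Each pathway reaction is reduced to an *elementary
reaction*: one reactant protein group, one product protein group,
small molecules discarded. Multi-protein complexes are split into
their members, and every reactant protein r is connected to every
different product protein p with a directed edge r → p following the
reaction stream; self-connections are excluded and duplicate relations
are stored once. A pair linked in both directions (a *bidirectional
pair*) signals proteins that act together in a complex.

**Centralities.** For a node v with node set V:

- degree  C_deg(v) = Σ_{u≠v} d(v,u), where d(v,u)=1 iff u and v are
  joined by an arrow in either direction (a bidirectional pair counts
  once);
- betweenness  C_bet(v) = Σ_{u≠v≠w} σ_{u,w}(v)/σ_{u,w}, the fraction
  of shortest u→w paths through v, summed over ordered pairs
  (unweighted, raw counts; unconnected pairs contribute 0);
- closeness  C_clo(v) = Σ_u dis(v,u) / Σ_u n(v,u), the **mean
  distance** from v to the nodes it can reach — lower means more
  central, and an isolated node scores 0.

**Degree distribution.** p(k), the fraction of nodes with degree k, is
fitted to a power law p(k) = A·k^(−γ) by log–log least squares (with a
discrete maximum-likelihood alternative). Scale-free structure means a
few hubs carry most connections.

**Modules.** Louvain modularity maximisation on the undirected
projection, with modules reported largest-first and each module's
highest-degree members as its *modular hubs*.

**Robustness.** A fraction f of nodes is removed at random (failure),
by degree rank (hub attack), or by betweenness rank (bridge attack);
the curves S(f) — largest remaining component over original size — and
⟨s⟩(f) — mean size of the other components — quantify fragmentation.

A synthetic generator emulates a curated reaction export at the
published network's scale (three subsystems, planted multifunctional
proteins, complexes, preferential hub reuse, cascade chaining), so the
whole pipeline is testable without external data.

## Worked example

```bash
thrombonet simulate --seed 7 --out reactions.tsv
thrombonet centrality --input reactions.tsv --out centrality.tsv
thrombonet fit --input reactions.tsv --out fit.json
thrombonet modules --input reactions.tsv --seed 7 --outdir mods
thrombonet robustness --input reactions.tsv --seed 7 --outdir rob
```

prints

```
wrote 200 reactions to reactions.tsv
150 nodes, 326 edges, average degree 2.17, average shortest path 3.76, 1 components
gamma = 1.160 (r^2 = 0.790, p = 2.1e-05)
7 modules, Q = 0.5575
random: S(fmax) = 0.863
hub: S(fmax) = 0.113
bridge: S(fmax) = 0.247
```

Reading: the synthetic network has 150 proteins and 326 directed
relations (average degree = edges/nodes = 2.17); its degree
distribution is heavy-tailed with exponent γ ≈ 1.16; Louvain finds 7
modules at modularity Q ≈ 0.56; and after removing 10% of nodes the
largest component keeps 86% of the network under random failure but
only 11% under a hub attack — the signature fragility of a scale-free
disease network, which is what makes hubs and bridges attractive drug
targets. The centrality table ranks every protein by degree with its
betweenness, closeness, subsystem annotations, and hub /
multifunctional flags:

```
#rank  node  degree  betweenness  closeness  functions    multifunctional  hub
1      P080  38      2841.56      2.63291    platelet     0                1
2      P092  33      969          1.09091    coagulation  0                1
...
```

The same stages are available as library calls
(`thrombonet.generate_reactions`, `build_network`, `centrality_table`,
`fit_power_law`, `louvain`, `simulate_removal`, …), and
`thrombonet all --synthetic --seed 7 --outdir out` runs everything and
writes a complete report bundle with a reproducibility manifest.

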