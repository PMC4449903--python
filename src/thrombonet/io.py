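"""Readers and writers for reaction sets, networks, and result tables.

All tabular output is TSV with a single ``#``-prefixed header line so
files are diff-friendly and bit-stable; set-valued fields are sorted
before joining.  GraphML export goes through networkx with a
``functions`` node attribute (``;``-joined subsystems) and a
``bidirectional`` edge attribute.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import ReactionParseError
from .network_builder import ElementaryReaction, ProteinNetwork

# ---------------------------------------------------------------------------
# Elementary reactions


def reactions_to_tsv(reactions: Iterable[ElementaryReaction]) -> str:
    lines = ["#reaction_id\tsubsystem\treactants\tproducts"]
    for r in reactions:
        lines.append(
            f"{r.reaction_id}\t{r.subsystem}\t"
            f"{';'.join(sorted(r.reactants))}\t{';'.join(sorted(r.products))}"
        )
    return "\n".join(lines) + "\n"


def reactions_from_tsv(text: str) -> list[ElementaryReaction]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ReactionParseError(parts[0] if parts else "?", f"expected 4 tab-separated fields, got {len(parts)}")
        rid, subsystem, reactants, products = parts
        out.append(
            ElementaryReaction(
                reaction_id=rid.strip(),
                reactants=frozenset(p.strip() for p in reactants.split(";") if p.strip()),
                products=frozenset(p.strip() for p in products.split(";") if p.strip()),
                subsystem=subsystem.strip(),
            )
        )
    return out


def reactions_to_json(reactions: Iterable[ElementaryReaction]) -> str:
    return json.dumps(
        [
            {
                "reaction_id": r.reaction_id,
                "subsystem": r.subsystem,
                "reactants": sorted(r.reactants),
                "products": sorted(r.products),
            }
            for r in reactions
        ],
        indent=2,
    )


def reactions_from_json(text: str) -> list[ElementaryReaction]:
    return [
        ElementaryReaction(
            reaction_id=d["reaction_id"],
            reactants=frozenset(d["reactants"]),
            products=frozenset(d["products"]),
            subsystem=d["subsystem"],
        )
        for d in json.loads(text)
    ]


def write_reactions(reactions: Iterable[ElementaryReaction], path: str | Path) -> None:
    path = Path(path)
    reactions = list(reactions)
    if path.suffix == ".json":
        path.write_text(reactions_to_json(reactions) + "\n")
    else:
        path.write_text(reactions_to_tsv(reactions))


def read_reactions(path: str | Path) -> list[ElementaryReaction]:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return reactions_from_json(text)
    return reactions_from_tsv(text)


# ---------------------------------------------------------------------------
# Networks


def write_network_tsv(
    network: ProteinNetwork, edge_path: str | Path, node_path: str | Path
) -> None:
    """Edge list (`source target bidirectional_flag`) plus node table."""
    bidir = network.bidirectional_pairs
    lines = ["#source\ttarget\tbidirectional"]
    for u, v in sorted(network.edges):
        flag = 1 if frozenset((u, v)) in bidir else 0
        lines.append(f"{u}\t{v}\t{flag}")
    Path(edge_path).write_text("\n".join(lines) + "\n")
    nlines = ["#node\tsubsystems"]
    for n in sorted(network.nodes):
        nlines.append(f"{n}\t{';'.join(sorted(network.node_functions.get(n, ())))}")
    Path(node_path).write_text("\n".join(nlines) + "\n")


def read_network_tsv(
    edge_path: str | Path, node_path: str | Path | None = None
) -> ProteinNetwork:
    edges = set()
    for line in Path(edge_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        edges.add((parts[0], parts[1]))
    nodes = {u for e in edges for u in e}
    functions: dict[str, frozenset[str]] = {}
    if node_path is not None:
        for line in Path(node_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0]
            subs = parts[1] if len(parts) > 1 else ""
            nodes.add(name)
            functions[name] = frozenset(s for s in subs.split(";") if s)
    return ProteinNetwork(frozenset(nodes), frozenset(edges), functions)


def write_network_graphml(network: ProteinNetwork, path: str | Path) -> None:
    g = network.to_digraph()
    bidir = network.bidirectional_pairs
    for n in g.nodes:
        g.nodes[n]["functions"] = ";".join(sorted(network.node_functions.get(n, ())))
    for u, v in g.edges:
        g.edges[u, v]["bidirectional"] = frozenset((u, v)) in bidir
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> ProteinNetwork:
    g = nx.read_graphml(str(path))
    functions = {
        str(n): frozenset(s for s in str(d.get("functions", "")).split(";") if s)
        for n, d in g.nodes(data=True)
    }
    return ProteinNetwork(
        frozenset(str(n) for n in g.nodes),
        frozenset((str(u), str(v)) for u, v in g.edges),
        functions,
    )


# ---------------------------------------------------------------------------
# Result tables


def centrality_table_to_tsv(records) -> str:
    lines = ["#rank\tnode\tdegree\tbetweenness\tcloseness\tfunctions\tmultifunctional\thub"]
    for rank, r in enumerate(records, start=1):
        lines.append(
            f"{rank}\t{r.node}\t{r.degree}\t{r.betweenness:.6g}\t{r.closeness:.6g}\t"
            f"{';'.join(sorted(r.functions))}\t{int(r.is_multifunctional)}\t{int(r.is_hub)}"
        )
    return "\n".join(lines) + "\n"


def partition_to_tsv(partition) -> str:
    lines = ["#node\tmodule"]
    for n in sorted(partition.assignment):
        lines.append(f"{n}\t{partition.assignment[n]}")
    return "\n".join(lines) + "\n"


def module_report_to_tsv(partition) -> str:
    lines = ["#module\tsize\thubs"]
    for c in sorted(partition.module_sizes):
        hubs = ";".join(partition.modular_hubs.get(c, []))
        lines.append(f"{c}\t{partition.module_sizes[c]}\t{hubs}")
    return "\n".join(lines) + "\n"


def robustness_curve_to_tsv(curve) -> str:
    lines = ["#mode\tf\tS\ts_avg"]
    for f, S, s in zip(curve.f_values, curve.S_values, curve.s_avg_values):
        lines.append(f"{curve.mode}\t{f:.6g}\t{S:.6g}\t{s:.6g}")
    return "\n".join(lines) + "\n"
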