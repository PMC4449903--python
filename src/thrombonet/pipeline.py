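"""End-to-end analysis pipeline: build -> centralities -> fit -> modules -> robustness.

One :class:`RunConfig` drives a full, reproducible run.  All
randomness flows from a single top-level seed that is split
deterministically into per-stage seeds (generator, Louvain, random
failure), so a run is reproduced by one integer.  Every artefact is a
text file (TSV/JSON/GraphML) written into the output directory along
with a machine-readable manifest of all parameters and derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .centrality import centrality_table, compare_groups, summarize
from .community import louvain
from .degree_distribution import empirical_pk, fit_power_law, fit_report
from .errors import ConfigurationError
from .network_builder import ProteinNetwork, build_network, multifunctional_nodes
from .robustness import (
    DEFAULT_FMAX,
    DEFAULT_REPLICATES,
    RemovalPlan,
    default_f_grid,
    fragmentation_threshold,
    simulate_removal,
)
from .synthetic_data import GeneratorConfig, generate_reactions

logger = logging.getLogger("thrombonet")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input source must be given: a reaction file
    (``reactions_path``), an edge list (``edgelist_path``, with an
    optional ``node_table_path``), a GraphML file (``graphml_path``),
    or a synthetic :class:`GeneratorConfig` (``generator``).
    """

    reactions_path: str | None = None
    edgelist_path: str | None = None
    node_table_path: str | None = None
    graphml_path: str | None = None
    generator: GeneratorConfig | None = None

    direction_mode: str = "directed"
    hub_threshold: int = 10
    resolution: float = 1.0
    modes: tuple[str, ...] = ("random", "hub", "bridge")
    fmax: float = DEFAULT_FMAX
    replicates: int = DEFAULT_REPLICATES
    adaptive: bool = False
    seed: int = 0
    outdir: str = "thrombonet_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        sources = [
            s
            for s in (
                self.reactions_path,
                self.edgelist_path,
                self.graphml_path,
                self.generator,
            )
            if s is not None
        ]
        if len(sources) != 1:
            raise ConfigurationError(
                f"exactly one input source must be specified, got {len(sources)}"
            )
        if self.generator is not None:
            self.generator.validate()
        if self.direction_mode not in ("directed", "undirected"):
            raise ConfigurationError("direction_mode must be 'directed' or 'undirected'")
        for m in self.modes:
            if m not in ("random", "hub", "bridge"):
                raise ConfigurationError(f"unknown removal mode {m!r}")
        if not 0 < self.fmax <= 1:
            raise ConfigurationError("fmax must be in (0, 1]")


def stage_seeds(seed: int, n: int = 3) -> list[int]:
    """Split one top-level seed into ``n`` independent stage seeds (< 2^31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML/JSON key-value document."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    gen = data.pop("generator", None)
    if gen is not None:
        if "complex_size_probs" in gen:
            gen["complex_size_probs"] = {
                int(k): float(v) for k, v in gen["complex_size_probs"].items()
            }
        if "subsystem_weights" in gen:
            gen["subsystem_weights"] = tuple(gen["subsystem_weights"])
        gen = GeneratorConfig(**gen)
    if "modes" in data:
        data["modes"] = tuple(data["modes"])
    return RunConfig(generator=gen, **data)


def _load_network(config: RunConfig, gen_seed: int) -> ProteinNetwork:
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=gen_seed)
        reactions = generate_reactions(gen)
        logger.info("generated %d synthetic reactions", len(reactions))
        return build_network(reactions)
    if config.reactions_path is not None:
        reactions = io.read_reactions(config.reactions_path)
        logger.info("read %d reactions from %s", len(reactions), config.reactions_path)
        return build_network(reactions)
    if config.graphml_path is not None:
        return io.read_network_graphml(config.graphml_path)
    return io.read_network_tsv(config.edgelist_path, config.node_table_path)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict with the in-memory results (network, centrality
    records, summary, fit, partition, robustness curves) keyed by
    stage name; the same content is written to ``config.outdir``.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_seed, louvain_seed, robust_seed = stage_seeds(config.seed)
    manifest: dict = {
        "config": _config_dict(config),
        "stage_seeds": {
            "generator": gen_seed,
            "louvain": louvain_seed,
            "robustness_random": robust_seed,
        },
        "stages": {},
    }

    stage = "network"
    try:
        return _run_stages(config, outdir, manifest, gen_seed, louvain_seed, robust_seed)
    except Exception:
        # preserve partial outputs and mark where the run broke off
        stage = manifest.get("current_stage", stage)
        manifest["stages"]["failed"] = stage
        manifest.pop("current_stage", None)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise


def _run_stages(
    config: RunConfig,
    outdir: Path,
    manifest: dict,
    gen_seed: int,
    louvain_seed: int,
    robust_seed: int,
) -> dict:
    manifest["current_stage"] = "network"
    try:
        network = _load_network(config, gen_seed)
    except OSError as exc:
        raise ConfigurationError(f"unreadable input: {exc}") from exc
    logger.info("network: %d nodes, %d edges", network.n_nodes, network.n_edges)
    io.write_network_tsv(network, outdir / "network_edges.tsv", outdir / "network_nodes.tsv")
    io.write_network_graphml(network, outdir / "network.graphml")
    manifest["stages"]["network"] = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
    }

    manifest["current_stage"] = "centrality"
    records = centrality_table(
        network, direction_mode=config.direction_mode, hub_threshold=config.hub_threshold
    )
    (outdir / "centrality.tsv").write_text(io.centrality_table_to_tsv(records))
    summary = summarize(network)
    comparison = compare_groups(records)
    (outdir / "summary.json").write_text(
        json.dumps(
            {
                **dataclasses.asdict(summary),
                "n_multifunctional": len(multifunctional_nodes(network)),
                "n_hubs": sum(r.is_hub for r in records),
                "group_comparison": comparison.group_means,
            },
            indent=2,
        )
        + "\n"
    )
    logger.info(
        "centralities for %d nodes (%d hubs at threshold %d)",
        len(records),
        sum(r.is_hub for r in records),
        config.hub_threshold,
    )

    manifest["current_stage"] = "degree_fit"
    dist = empirical_pk({r.node: r.degree for r in records})
    try:
        fit = fit_power_law(dist)
        fit_payload = fit_report(dist, fit)
    except Exception as exc:  # degenerate degree spectra stay reportable
        fit = None
        fit_payload = {"pk": {str(k): p for k, p in dist.pk.items()}, "error": str(exc)}
    (outdir / "degree_fit.json").write_text(json.dumps(fit_payload, indent=2) + "\n")

    manifest["current_stage"] = "modules"
    partition = louvain(network, resolution=config.resolution, seed=louvain_seed)
    (outdir / "modules.tsv").write_text(io.partition_to_tsv(partition))
    (outdir / "module_report.tsv").write_text(io.module_report_to_tsv(partition))
    logger.info("%d modules, Q = %.4f", partition.n_modules, partition.modularity)

    manifest["current_stage"] = "robustness"
    f_grid = default_f_grid(network.n_nodes, config.fmax)
    curves = {}
    for mode in config.modes:
        plan = RemovalPlan(
            mode=mode,
            f_grid=f_grid,
            replicates=config.replicates,
            seed=robust_seed,
            adaptive=config.adaptive,
        )
        curve = simulate_removal(network, plan)
        curves[mode] = curve
        (outdir / f"robustness_{mode}.tsv").write_text(io.robustness_curve_to_tsv(curve))
    (outdir / "robustness.json").write_text(
        json.dumps(
            {
                mode: {
                    "f": list(c.f_values),
                    "S": list(c.S_values),
                    "s_avg": list(c.s_avg_values),
                    "replicates": c.replicate_count,
                    "fragmentation_threshold": fragmentation_threshold(c),
                }
                for mode, c in curves.items()
            },
            indent=2,
        )
        + "\n"
    )
    logger.info("robustness curves for modes: %s", ", ".join(curves))

    manifest.pop("current_stage", None)
    manifest["stages"].update(
        {
            "centrality": {"n_records": len(records)},
            "degree_fit": {"gamma": None if fit is None else fit.gamma},
            "modules": {"n_modules": partition.n_modules, "Q": partition.modularity},
            "robustness": {"modes": list(curves), "f_grid_len": len(f_grid)},
        }
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "network": network,
        "records": records,
        "summary": summary,
        "comparison": comparison,
        "distribution": dist,
        "fit": fit,
        "partition": partition,
        "curves": curves,
        "manifest": manifest,
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.generator is not None:
        d["generator"] = dataclasses.asdict(config.generator)
    d["modes"] = list(config.modes)
    return d
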