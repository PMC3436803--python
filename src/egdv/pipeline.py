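"""End-to-end pipeline: GDV -> similarity -> clustering -> quality/enrichment.

The pipeline wires the library modules into the four clustering strategies
(node-HIE, edge-HIE, node-KM, edge-KM).  GDVs are always computed on the
full input graph; clustering and all downstream analyses restrict to nodes
of degree > min_degree and to edges whose both endpoints pass.

Defaults follow the original human-network protocol: min_degree 3,
K_HIE 1250, K_KM 1000, enrichment threshold k = 66%, alpha 0.05, 100
randomization runs.  On small inputs K is clamped to the item count with a
logged note.  Every run produces a JSON-serializable summary that is
reproducible given the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import cluster as cl
from . import enrichment as en
from . import io as eio
from . import quality as q
from .atlas import edge_orbit_dependencies, node_orbit_dependencies
from .gdv import count_edge_gdv, count_node_gdv
from .similarity import gdv_similarity_matrix

log = logging.getLogger(__name__)

STRATEGIES = ("node-hie", "edge-hie", "node-km", "edge-km")


@dataclass
class PipelineConfig:
    graph: str = "edges.tsv"
    annotations: str | None = None
    pathogens: str | None = None
    out_dir: str = "egdv_out"
    strategy: str = "edge-hie"
    min_degree: int = 3
    K_hie: int = 1250
    K_km: int = 1000
    enrichment_k: float = 66.0
    alpha: float = 0.05
    baseline_runs: int = 100
    adjacent_only: bool = False
    recompute_significance: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def cluster_items(
    graph: nx.Graph,
    strategy: str,
    min_degree: int = 3,
    K: int | None = None,
    seed: int = 0,
    adjacent_only: bool = False,
):
    """Run one clustering strategy; returns (partition, item list, sim matrix)."""
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    mode = "edge" if strategy.startswith("edge") else "node"
    kept_nodes, kept_edges = cl.degree_filter(graph, min_degree)
    if mode == "edge":
        gdv = count_edge_gdv(graph)
        items = sorted(kept_edges)
        weights = edge_orbit_dependencies()
    else:
        gdv = count_node_gdv(graph)
        items = sorted(kept_nodes, key=str)
        weights = node_orbit_dependencies()
    if not items:
        raise ValueError(f"no items of degree > {min_degree} to cluster")
    sim = gdv_similarity_matrix(gdv.subset(items), weights, adjacent_only=adjacent_only)
    if K is None:
        K = 1250 if strategy.endswith("hie") else 1000
    if K > len(items):
        log.info("K=%d exceeds %d items; clamping", K, len(items))
        K = len(items)
    if strategy.endswith("hie"):
        dend = cl.single_linkage(items, sim)
        part = cl.cut(dend, K, kind=mode)
    else:
        part, _ = cl.k_medoids(items, K, 1.0 - sim, seed=seed, kind=mode)
    return part, items, sim


def run_pipeline(config: PipelineConfig, graph=None, annotations=None, pathogen_map=None):
    """Execute the configured strategy end to end and write artifacts.

    Inputs may be passed as objects or read from the configured paths.
    Returns the summary dict (also written as summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if graph is None:
        graph, _ = eio.read_edge_list(config.graph)
    if annotations is None and config.annotations:
        annotations = eio.read_annotations(config.annotations)
    if pathogen_map is None and config.pathogens:
        pathogen_map = eio.read_pathogen_map(config.pathogens)

    summary: dict = {
        "config": dataclasses.asdict(config),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }
    mode = "edge" if config.strategy.startswith("edge") else "node"
    K = config.K_hie if config.strategy.endswith("hie") else config.K_km
    part, items, _ = cluster_items(
        graph,
        config.strategy,
        min_degree=config.min_degree,
        K=K,
        seed=config.seed,
        adjacent_only=config.adjacent_only,
    )
    eio.write_partition(part, out / "partition.tsv")
    summary["n_items_clustered"] = len(items)
    summary["K"] = part.K
    if mode == "edge":
        d, _ = cl.partition_density(part)
        summary["partition_density"] = d

    clusters = part.node_clusters()
    if annotations:
        universe = set().union(*clusters.values())
        report = q.quality_report(clusters, universe, annotations)
        summary["quality"] = {
            "cc": report.cc,
            "oc": report.oc,
            "cq": report.cq,
            "oq": report.oq,
        }
    if pathogen_map is not None:
        universe, pmap = en.eligible_universe(graph, pathogen_map, config.min_degree)
        summary["n_pi_proteins"] = len(universe)
        summary["n_pathogens"] = len(pmap.pathogen_to_proteins)
        curve = en.loocv_pr_curve(
            clusters, pmap, universe, config.alpha, config.recompute_significance
        )
        curve.to_frame().to_csv(out / "pr_curve.tsv", sep="\t", index=False)
        summary["pr_at_k"] = curve.at(int(config.enrichment_k))
        baseline = en.random_baseline(
            clusters, pmap, universe, runs=config.baseline_runs, seed=config.seed,
            alpha=config.alpha,
        )
        baseline.to_frame().to_csv(out / "pr_curve_random.tsv", sep="\t", index=False)
        summary["random_f_at_k"] = float(baseline.f_score[int(config.enrichment_k)])
        records = en.enrichment_table(clusters, pmap, universe)
        eio.write_enrichment_table(records, out / "enrichment.tsv")
        preds = en.predict_new(
            clusters, pmap, universe, config.enrichment_k, config.alpha,
            method=config.strategy,
        )
        eio.write_predictions(preds, out / "predictions.tsv")
        summary["n_predictions"] = len(preds)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def run_multi_strategy(config: PipelineConfig, strategies, graph=None, pathogen_map=None):
    """Run several strategies and merge their predictions with provenance."""
    per_method: dict = {}
    summaries: dict = {}
    for strat in strategies:
        cfg = dataclasses.replace(
            config, strategy=strat, out_dir=str(Path(config.out_dir) / strat)
        )
        summaries[strat] = run_pipeline(cfg, graph=graph, pathogen_map=pathogen_map)
        preds_path = Path(cfg.out_dir) / "predictions.tsv"
        if preds_path.exists():
            import pandas as pd

            df = pd.read_csv(preds_path, sep="\t")
            per_method[strat] = [
                en.Prediction(r.protein, r.pathogen, [], r.enrichment, r.p_value)
                for r in df.itertuples(index=False)
            ]
    merged = en.merge_predictions(per_method)
    eio.write_predictions(merged, Path(config.out_dir) / "predictions_merged.tsv")
    overlap = {}
    for n_methods in range(1, len(strategies) + 1):
        overlap[n_methods] = sum(1 for p in merged if len(p.methods) == n_methods)
    return {"per_strategy": summaries, "n_merged": len(merged), "overlap": overlap}
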