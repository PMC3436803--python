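"""TSV readers and writers for graphs, annotations, pathogen maps and results.

All formats are plain tab-separated text: edge lists and annotation /
pathogen association tables are two-column files with ``#`` comment lines
ignored; node identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .cluster import Partition
from .enrichment import PathogenMap

log = logging.getLogger(__name__)


def _read_two_columns(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    return df.iloc[:, :2]


def read_edge_list(path) -> tuple[nx.Graph, int]:
    """Read an undirected simple graph; returns (graph, warning count).

    Self-loops and duplicate edges (in either orientation) are dropped,
    each counted as one warning.
    """
    g = nx.Graph()
    warnings = 0
    try:
        df = _read_two_columns(path)
    except pd.errors.EmptyDataError:
        return g, 0
    for a, b in df.itertuples(index=False):
        if a == b:
            warnings += 1
            continue
        if g.has_edge(a, b):
            warnings += 1
            continue
        g.add_edge(a, b)
    if warnings:
        log.warning("%s: dropped %d self-loop/duplicate row(s)", path, warnings)
    return g, warnings


def read_annotations(path) -> dict:
    """node -> set of term ids (terms are opaque strings)."""
    out: dict = {}
    try:
        df = _read_two_columns(path)
    except pd.errors.EmptyDataError:
        return out
    for node, term in df.itertuples(index=False):
        out.setdefault(node, set()).add(term)
    return out


def read_pathogen_map(path) -> PathogenMap:
    try:
        df = _read_two_columns(path)
    except pd.errors.EmptyDataError:
        return PathogenMap(frozenset())
    return PathogenMap.from_pairs(df.itertuples(index=False))


def _item_label(item) -> str:
    return f"{item[0]}|{item[1]}" if isinstance(item, tuple) else str(item)


def write_partition(partition: Partition, path) -> None:
    rows = sorted(
        (_item_label(item), cid) for item, cid in partition.assignment.items()
    )
    pd.DataFrame(rows, columns=["item", "cluster"]).to_csv(path, sep="\t", index=False)


def read_partition(path, kind: str = "node") -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"item": str, "cluster": int})
    assignment = {}
    for item, cid in df.itertuples(index=False):
        if kind == "edge":
            a, b = item.split("|")
            assignment[(a, b)] = int(cid)
        else:
            assignment[item] = int(cid)
    return Partition(assignment, kind)


def write_dendrogram(dendrogram, path) -> None:
    pd.DataFrame(
        dendrogram.merges, columns=["cluster_a", "cluster_b", "similarity"]
    ).to_csv(path, sep="\t", index=False)


def write_predictions(predictions, path) -> None:
    rows = [
        (
            p.protein,
            p.pathogen,
            ";".join(map(str, p.clusters)),
            p.enrichment,
            p.p_value,
            ";".join(p.methods),
        )
        for p in predictions
    ]
    pd.DataFrame(
        rows,
        columns=["protein", "pathogen", "clusters", "enrichment", "p_value", "methods"],
    ).to_csv(path, sep="\t", index=False)


def write_enrichment_table(records, path) -> None:
    rows = [
        (r.cluster, r.pathogen, r.N, r.P, r.C, r.p, r.enrichment, r.p_value)
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["cluster", "pathogen", "N", "P", "C", "p", "enrichment", "p_value"]
    ).to_csv(path, sep="\t", index=False)
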