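"""Topological similarity measures: GDV-similarity and edge-SN.

The GDV-similarity between two orbit-count vectors e and f is

    S(e, f) = 1 - D(e, f),
    D(e, f) = sum_i D_i / sum_i w_i,
    D_i = w_i * |log(e_i + 1) - log(f_i + 1)| / log(max(e_i, f_i) + 2),

with orbit-dependency weights w_i from the atlas.  The log scaling keeps
order-of-magnitude count differences from dominating and measures relative
rather than absolute disagreement; the +1/+2 constants keep every term
finite and strictly below w_i, so S lies in (0, 1] and equals 1 exactly for
identical vectors.  The same form serves edges (68 orbits, weights
normalized by log 68) and nodes (73 orbits, log 73).

edge-SN is the shared-neighborhood similarity of two *adjacent* edges e_ik,
e_jk: the Jaccard index of the inclusive neighborhoods n(i), n(j) of the
two non-shared endpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .atlas import OrbitWeights, edge_orbit_dependencies, node_orbit_dependencies
from .gdv import GDVMatrix


def gdv_distance_component(e_i: int, f_i: int, w_i: float) -> float:
    """Weighted per-orbit distance; lies in [0, w_i)."""
    if e_i < 0 or f_i < 0:
        raise ValueError("orbit counts must be non-negative")
    return w_i * abs(np.log(e_i + 1.0) - np.log(f_i + 1.0)) / np.log(max(e_i, f_i) + 2.0)


def _gdv_similarity(u: np.ndarray, v: np.ndarray, weights: OrbitWeights) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.shape[0] != weights.w.shape[0]:
        raise ValueError(f"expected vectors of length {weights.w.shape[0]}")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("orbit counts must be non-negative")
    d = weights.w * np.abs(np.log(u + 1.0) - np.log(v + 1.0)) / np.log(np.maximum(u, v) + 2.0)
    return float(1.0 - d.sum() / weights.w.sum())


def edge_gdv_similarity(gdv_e, gdv_f, weights: OrbitWeights | None = None) -> float:
    """edge-GDV-similarity S(e, f) in (0, 1] between two 68-element vectors."""
    if weights is None:
        weights = edge_orbit_dependencies()
    return _gdv_similarity(gdv_e, gdv_f, weights)


def node_gdv_similarity(gdv_u, gdv_v, weights: OrbitWeights | None = None) -> float:
    """node-GDV-similarity in (0, 1] between two 73-element vectors."""
    if weights is None:
        weights = node_orbit_dependencies()
    return _gdv_similarity(gdv_u, gdv_v, weights)


def edge_sn_similarity(graph: nx.Graph, edge_ik, edge_jk) -> float:
    """Shared-neighborhood similarity of two adjacent edges.

    With common node k and non-shared endpoints i, j, returns
    |n(i) ∩ n(j)| / |n(i) ∪ n(j)| over inclusive neighborhoods.
    """
    a = set(edge_ik)
    b = set(edge_jk)
    if a == b:
        raise ValueError("edges must be distinct")
    shared = a & b
    if len(shared) != 1:
        raise ValueError("edges must share exactly one endpoint")
    (i,) = a - shared
    (j,) = b - shared
    ni = set(graph[i]) | {i}
    nj = set(graph[j]) | {j}
    return len(ni & nj) / len(ni | nj)


def _adjacency_mask(items: list) -> np.ndarray:
    """Boolean matrix marking edge pairs that share an endpoint."""
    n = len(items)
    mask = np.zeros((n, n), dtype=bool)
    by_node: dict = {}
    for idx, (a, b) in enumerate(items):
        by_node.setdefault(a, []).append(idx)
        by_node.setdefault(b, []).append(idx)
    for idxs in by_node.values():
        for x in idxs:
            for y in idxs:
                if x != y:
                    mask[x, y] = True
    return mask


def gdv_similarity_matrix(
    gdv: GDVMatrix,
    weights: OrbitWeights | None = None,
    adjacent_only: bool = False,
) -> np.ndarray:
    """Dense pairwise GDV-similarity matrix over `gdv.items`.

    With ``adjacent_only`` (edge items), non-adjacent pairs are set to 0 —
    the minimum — reproducing adjacent-edge-only clustering; otherwise all
    pairs are compared regardless of adjacency.
    """
    if weights is None:
        weights = edge_orbit_dependencies() if gdv.kind == "edge" else node_orbit_dependencies()
    c = gdv.counts.astype(float)
    n, m = c.shape
    if m != weights.w.shape[0]:
        raise ValueError("GDV width does not match weight vector")
    logc = np.log(c + 1.0)
    wsum = weights.w.sum()
    sim = np.empty((n, n))
    for i in range(n):
        diff = np.abs(logc[i] - logc)  # (n, m)
        denom = np.log(np.maximum(c[i], c) + 2.0)
        d = (weights.w * diff / denom).sum(axis=1) / wsum
        sim[i] = 1.0 - d
    np.fill_diagonal(sim, 1.0)
    if adjacent_only:
        if gdv.kind != "edge":
            raise ValueError("adjacent_only applies to edge GDVs")
        mask = _adjacency_mask(gdv.items)
        sim = np.where(mask, sim, 0.0)
        np.fill_diagonal(sim, 1.0)
    return sim


def edge_sn_matrix(graph: nx.Graph, items: list | None = None) -> np.ndarray:
    """Pairwise edge-SN similarity over edges; non-adjacent pairs are 0."""
    if items is None:
        items = sorted(tuple(sorted(e, key=str)) for e in graph.edges)
    n = len(items)
    sim = np.zeros((n, n))
    np.fill_diagonal(sim, 1.0)
    mask = _adjacency_mask(items)
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                s = edge_sn_similarity(graph, items[i], items[j])
                sim[i, j] = sim[j, i] = s
    return sim


def similarity_long_frame(items: list, sim: np.ndarray) -> pd.DataFrame:
    """Long-format (item_a, item_b, similarity) table for TSV export."""

    def label(x):
        return f"{x[0]}|{x[1]}" if isinstance(x, tuple) else str(x)

    rows = [
        (label(items[i]), label(items[j]), sim[i, j])
        for i in range(len(items))
        for j in range(i + 1, len(items))
    ]
    return pd.DataFrame(rows, columns=["item_a", "item_b", "similarity"])
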