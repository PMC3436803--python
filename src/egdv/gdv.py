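"""Graphlet degree vector (GDV) counting for nodes and edges.

For every node v of a network, the node-GDV counts, per node orbit, the
connected induced subgraphs on 2-5 nodes that contain v with v sitting at
that orbit (element 0 is the degree).  For every edge, the edge-GDV counts
the connected induced 3-5-node subgraphs through the edge, per edge orbit
(orbit 0 — the edge itself — is excluded, so edge-GDVs have 68 elements
for orbits 1..68).

Counting enumerates each connected induced subgraph exactly once with the
ESU extension scheme and classifies it through a precomputed lookup table
keyed by the labelled adjacency bitmask, which maps every position of the
subgraph to its global orbit id.  Correctness is pinned in the test suite
to a naive subset-enumeration oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import (
    MAX_NODES,
    N_EDGE_ORBITS,
    N_NODE_ORBITS,
    _canonical_key,
    _is_connected,
    _norm_edge,
    build_atlas,
)

log = logging.getLogger(__name__)

EDGE_ORBIT_OFFSET = 1  # edge-GDV column j holds orbit j+1


@dataclass
class GDVMatrix:
    """Orbit-count vectors for an ordered list of nodes or edges."""

    kind: str  # "node" | "edge"
    items: list
    counts: np.ndarray  # shape (len(items), 73) or (len(items), 68)

    def __post_init__(self):
        self._index = {item: i for i, item in enumerate(self.items)}

    def vector(self, item) -> np.ndarray:
        return self.counts[self._index[item]]

    def subset(self, items) -> "GDVMatrix":
        items = list(items)
        rows = [self._index[i] for i in items]
        return GDVMatrix(self.kind, items, self.counts[rows])

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "node":
            ids = list(self.items)
            cols = [f"o{i}" for i in range(N_NODE_ORBITS)]
        else:
            ids = [f"{a}|{b}" for a, b in self.items]
            cols = [f"o{i + EDGE_ORBIT_OFFSET}" for i in range(N_EDGE_ORBITS - 1)]
        df = pd.DataFrame(self.counts, columns=cols)
        df.insert(0, "item", ids)
        return df


@lru_cache(maxsize=1)
def _classification_tables():
    """For each size k and labelled adjacency bitmask of a connected graph on
    nodes 0..k-1: (node orbit id per node, edge orbit id per pair index)."""
    graphlets, table = build_atlas()
    by_key = {_canonical_key(g.n, g.edges): g for g in graphlets}
    tables: dict[int, dict[int, tuple]] = {}
    for k in range(2, MAX_NODES + 1):
        pairs = list(combinations(range(k), 2))
        tab: dict[int, tuple] = {}
        for mask in range(1, 1 << len(pairs)):
            edges = frozenset(pairs[i] for i in range(len(pairs)) if mask >> i & 1)
            if any(v not in {x for e in edges for x in e} for v in range(k)):
                continue
            if not _is_connected(k, edges):
                continue
            g = by_key[_canonical_key(k, edges)]
            f = next(
                perm
                for perm in permutations(range(k))
                if frozenset(_norm_edge(perm[a], perm[b]) for a, b in edges) == g.edges
            )
            node_orb = tuple(table.node_orbits[(g.id, f[v])] for v in range(k))
            edge_orb = tuple(
                table.edge_orbits[(g.id, _norm_edge(f[a], f[b]))] if (a, b) in edges else -1
                for a, b in pairs
            )
            tab[mask] = (node_orb, edge_orb)
        tables[k] = tab
    return tables


def sanitize_graph(graph: nx.Graph) -> nx.Graph:
    """Drop self-loops (and collapse parallel edges) with a logged warning."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    loops = 0
    for a, b in graph.edges:
        if a == b:
            loops += 1
        else:
            g.add_edge(a, b)
    if loops:
        log.warning("dropped %d self-loop(s)", loops)
    return g


def _enumerate_connected_subsets(adj: list[set[int]], max_size: int = MAX_NODES):
    """Yield every connected node subset of size 2..max_size exactly once.

    ESU-style extension: grow from each root v using only higher-indexed
    nodes, extending with exclusive neighbors, so each subset appears at a
    unique position of the recursion tree.
    """
    n = len(adj)
    for v in range(n):
        sub = [v]
        in_sub_nbrs = set(adj[v])

        def extend(ext: list[int]):
            for idx, w in enumerate(ext):
                sub.append(w)
                if len(sub) >= 2:
                    yield tuple(sub)
                if len(sub) < max_size:
                    new_ext = ext[idx + 1 :] + [
                        u for u in adj[w] if u > v and u not in in_sub_nbrs and u != w
                    ]
                    added = [u for u in adj[w] if u not in in_sub_nbrs]
                    in_sub_nbrs.update(added)
                    yield from extend(new_ext)
                    in_sub_nbrs.difference_update(added)
                sub.pop()

        yield from extend([u for u in adj[v] if u > v])


def _prepare(graph: nx.Graph):
    nodes = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [set() for _ in nodes]
    for a, b in graph.edges:
        if a == b:
            continue
        adj[index[a]].add(index[b])
        adj[index[b]].add(index[a])
    return nodes, index, adj


def count_node_gdv(graph: nx.Graph) -> GDVMatrix:
    """Node-GDVs (73 orbit counts per node) over the full input graph."""
    nodes, _, adj = _prepare(graph)
    counts = np.zeros((len(nodes), N_NODE_ORBITS), dtype=np.int64)
    tables = _classification_tables()
    for sub in _enumerate_connected_subsets(adj):
        s = sorted(sub)
        k = len(s)
        mask = 0
        for i, (a, b) in enumerate(combinations(range(k), 2)):
            if s[b] in adj[s[a]]:
                mask |= 1 << i
        node_orb, _ = tables[k][mask]
        for pos, v in enumerate(s):
            counts[v, node_orb[pos]] += 1
    return GDVMatrix("node", nodes, counts)


def count_edge_gdv(graph: nx.Graph) -> GDVMatrix:
    """Edge-GDVs (68 orbit counts per edge, orbits 1..68) over the graph.

    Each connected induced 3-5-node subgraph increments exactly one orbit
    count of every edge it contains.
    """
    nodes, _, adj = _prepare(graph)
    edges = sorted((i, j) for i in range(len(nodes)) for j in adj[i] if i < j)
    edge_index = {e: i for i, e in enumerate(edges)}
    counts = np.zeros((len(edges), N_EDGE_ORBITS - 1), dtype=np.int64)
    tables = _classification_tables()
    for sub in _enumerate_connected_subsets(adj):
        if len(sub) < 3:
            continue
        s = sorted(sub)
        k = len(s)
        pairs = list(combinations(range(k), 2))
        mask = 0
        for i, (a, b) in enumerate(pairs):
            if s[b] in adj[s[a]]:
                mask |= 1 << i
        _, edge_orb = tables[k][mask]
        for i, (a, b) in enumerate(pairs):
            orb = edge_orb[i]
            if orb >= 0:
                counts[edge_index[(s[a], s[b])], orb - EDGE_ORBIT_OFFSET] += 1
    labelled = [(nodes[a], nodes[b]) for a, b in edges]
    labelled = [tuple(sorted(e, key=str)) for e in labelled]
    return GDVMatrix("edge", labelled, counts)
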