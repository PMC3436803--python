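"""Independent brute-force oracles used to pin the production algorithms.

These deliberately share no code path with the implementations they check:
GDV counts come from exhaustive subset enumeration with permutation-based
isomorphism matching, single-linkage partitions from connected components
of thresholded similarity graphs, and hypergeometric tails from exhaustive
enumeration of draws.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb

import networkx as nx
import numpy as np

from egdv.atlas import _canonical_key, _norm_edge, build_atlas


def naive_gdv_counts(graph: nx.Graph):
    """Node and edge orbit counts by iterating every 2-5-node subset.

    Returns (nodes, node_counts[73], edges, edge_counts[68]).
    """
    graphlets, table = build_atlas()
    by_key = {_canonical_key(g.n, g.edges): g for g in graphlets}
    nodes = sorted(graph.nodes, key=str)
    nidx = {v: i for i, v in enumerate(nodes)}
    ncounts = np.zeros((len(nodes), 73), dtype=int)
    edges = sorted(tuple(sorted(e, key=str)) for e in graph.edges)
    eidx = {e: i for i, e in enumerate(edges)}
    ecounts = np.zeros((len(edges), 68), dtype=int)
    for k in range(2, 6):
        for subset in combinations(nodes, k):
            sub = graph.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            local = {v: i for i, v in enumerate(subset)}
            es = frozenset(_norm_edge(local[a], local[b]) for a, b in sub.edges)
            g = by_key[_canonical_key(k, es)]
            f = next(
                p
                for p in permutations(range(k))
                if frozenset(_norm_edge(p[a], p[b]) for a, b in es) == g.edges
            )
            for v in subset:
                ncounts[nidx[v], table.node_orbits[(g.id, f[local[v]])]] += 1
            if k >= 3:
                for a, b in sub.edges:
                    orb = table.edge_orbits[(g.id, _norm_edge(f[local[a]], f[local[b]]))]
                    ecounts[eidx[tuple(sorted((a, b), key=str))], orb - 1] += 1
    return nodes, ncounts, edges, ecounts


def threshold_clusters(items: list, sim: np.ndarray, threshold: float):
    """Connected components of the graph keeping pairs with sim >= threshold.

    Single-linkage equivalence: cutting the dendrogram right after all
    merges at similarity >= t yields exactly these components.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(items)))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if sim[i, j] >= threshold:
                g.add_edge(i, j)
    return {frozenset(items[i] for i in comp) for comp in nx.connected_components(g)}


def exhaustive_hypergeom_tail(N: int, P: int, C: int, p: int) -> float:
    """P(X >= p) by summing the exact hypergeometric pmf over the tail."""
    total = comb(N, C)
    fav = sum(comb(P, x) * comb(N - P, C - x) for x in range(p, min(P, C) + 1))
    return fav / total
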