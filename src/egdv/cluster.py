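"""Similarity-driven clustering of nodes or edges.

Two clustering methods operate on a precomputed similarity matrix:

* single-linkage agglomeration (equivalently, maximum-spanning-tree
  threshold clustering), producing a dendrogram that is cut into K
  clusters, with partition-density-based automatic level selection for
  edge partitions;
* k-medoids with a fixed K on distance 1 - S.

Edge partitions induce *overlapping* node memberships: a node belongs to
the cluster of each of its clustered edges, which is the point of
clustering edges rather than nodes.

Tie-breaking is deterministic throughout: equal-similarity merges happen
in lexicographic item order, and a cut that lands inside a block of tied
merge levels completes the block (returning the nearest achievable
K' <= K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Single-linkage merge tree: leaves 0..n-1, merge t creates cluster n+t."""

    leaves: list
    merges: list[tuple[int, int, float]]  # (cluster_a, cluster_b, similarity)


@dataclass
class Partition:
    """Flat assignment of items to clusters."""

    assignment: dict  # item -> cluster id
    kind: str = "node"  # "node" | "edge"

    @property
    def K(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for item, cid in self.assignment.items():
            out.setdefault(cid, []).append(item)
        return out

    def node_clusters(self) -> dict[int, set]:
        """Cluster id -> set of member nodes.

        For edge partitions a cluster's node set is the union of its edges'
        endpoints, so nodes may belong to several clusters (overlap).
        """
        out: dict[int, set] = {}
        for item, cid in self.assignment.items():
            s = out.setdefault(cid, set())
            if self.kind == "edge":
                s.update(item)
            else:
                s.add(item)
        return out

    def node_memberships(self) -> dict:
        """Node -> set of cluster ids (overlapping for edge partitions)."""
        out: dict = {}
        for cid, nodes in self.node_clusters().items():
            for v in nodes:
                out.setdefault(v, set()).add(cid)
        return out


def single_linkage(items: list, sim: np.ndarray) -> Dendrogram:
    """Single-linkage agglomeration of `items` under a similarity matrix.

    Inter-cluster similarity is the maximum cross-pair similarity, so the
    merge sequence is the maximum-spanning-tree (Kruskal) order: pairs
    sorted by descending similarity, ties broken by lexicographic item ids.
    Pairs without a defined similarity should be encoded as 0.
    """
    n = len(items)
    if n == 0:
        raise ValueError("no items to cluster")
    if n == 1:
        return Dendrogram(list(items), [])
    order = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda p: (-sim[p[0], p[1]], items[p[0]], items[p[1]]),
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cluster_id = list(range(n))  # root -> current cluster id
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for i, j in order:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        merges.append((cluster_id[ri], cluster_id[rj], float(sim[i, j])))
        parent[ri] = rj
        cluster_id[rj] = next_id
        next_id += 1
        if len(merges) == n - 1:
            break
    return Dendrogram(list(items), merges)


def cut(dendrogram: Dendrogram, K: int, kind: str = "node") -> Partition:
    """Cut the merge tree into K clusters (nearest achievable K' <= K).

    Applies merges in order until K clusters remain; if the stopping point
    falls inside a run of equal-similarity merges, the whole tied block is
    applied, which may yield fewer clusters than requested.
    """
    n = len(dendrogram.leaves)
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    n_apply = n - K
    merges = dendrogram.merges
    while n_apply < len(merges) and n_apply > 0 and merges[n_apply][2] == merges[n_apply - 1][2]:
        n_apply += 1
    if n_apply != n - K:
        log.info("cut: tied merge levels, returning %d clusters instead of %d", n - n_apply, K)
    return _partition_after(dendrogram, n_apply, kind)


def _partition_after(dendrogram: Dendrogram, n_apply: int, kind: str) -> Partition:
    n = len(dendrogram.leaves)
    parent = list(range(n + n_apply))
    for t in range(n_apply):
        a, b, _ = dendrogram.merges[t]
        parent[a] = n + t
        parent[b] = n + t

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    roots: dict[int, int] = {}
    assignment = {}
    for i, item in enumerate(dendrogram.leaves):
        r = find(i)
        cid = roots.setdefault(r, len(roots))
        assignment[item] = cid
    return Partition(assignment, kind)


def partition_density(edge_partition: Partition, M: int | None = None):
    """Overall partition density D and per-cluster densities D_C.

    For a cluster with m_C edges over n_C distinct endpoints,
    D_C = [m_C - (n_C - 1)] / [n_C(n_C - 1)/2 - (n_C - 1)]  (0 if n_C = 2),
    and D = (2/M) sum_C m_C (m_C - (n_C - 1)) / ((n_C - 2)(n_C - 1)),
    the edge-count-weighted mean of the D_C.  D = 1 iff every cluster's
    edges saturate a clique on its node set.
    """
    if edge_partition.kind != "edge":
        raise ValueError("partition density is defined for edge partitions")
    clusters = edge_partition.clusters()
    if M is None:
        M = sum(len(edges) for edges in clusters.values())
    if M == 0:
        raise ValueError("empty edge partition")
    d_c: dict[int, float] = {}
    total = 0.0
    for cid, edges in clusters.items():
        m_c = len(edges)
        nodes = {v for e in edges for v in e}
        n_c = len(nodes)
        if n_c <= 2:
            d_c[cid] = 0.0
            continue
        d_c[cid] = (m_c - (n_c - 1)) / (n_c * (n_c - 1) / 2 - (n_c - 1))
        total += m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / M, d_c


def _cut_levels(dendrogram: Dendrogram):
    """Merge counts at tie-block boundaries (every achievable cut level)."""
    merges = dendrogram.merges
    levels = [0]
    for t in range(1, len(merges) + 1):
        if t == len(merges) or merges[t][2] != merges[t - 1][2]:
            levels.append(t)
    return levels


def select_partition(
    dendrogram: Dendrogram,
    strategy: str = "max_density",
    cc_cap: float | None = None,
    annotations: dict | None = None,
    node_universe: set | None = None,
    kind: str = "edge",
) -> Partition:
    """Scan all cut levels of the dendrogram and return the best partition.

    Strategies:

    * ``max_density`` — maximize partition density D (edge partitions);
    * ``max_density_cc_capped`` — maximize D among levels whose cluster
      coverage does not exceed ``cc_cap``;
    * ``best_overall_quality`` — maximize the sum of the four quality
      measures (CC, OC, CQ, OQ), each normalized by its maximum across the
      scanned levels; requires ``annotations`` and ``node_universe``.
    """
    from . import quality as q

    levels = _cut_levels(dendrogram)
    parts = [_partition_after(dendrogram, t, kind) for t in levels]
    if strategy in ("max_density", "max_density_cc_capped"):
        best = None
        best_d = -np.inf
        for part in parts:
            if strategy == "max_density_cc_capped":
                if cc_cap is None or node_universe is None:
                    raise ValueError("cc_cap and node_universe required")
                cc = q.cluster_coverage(part.node_clusters(), node_universe)
                if cc > cc_cap:
                    continue
            d, _ = partition_density(part)
            if d > best_d:
                best, best_d = part, d
        if best is None:
            raise ValueError("no cut level satisfies the CC cap")
        return best
    if strategy == "best_overall_quality":
        if annotations is None or node_universe is None:
            raise ValueError("annotations and node_universe required")
        reports = {
            i: q.quality_report(part.node_clusters(), node_universe, annotations)
            for i, part in enumerate(parts)
        }
        scored = q.normalize_and_score(reports)
        best_i = max(scored, key=lambda i: (scored[i].overall, i))
        return parts[best_i]
    raise ValueError(f"unknown strategy {strategy!r}")


def k_medoids(
    items: list,
    K: int,
    distance: np.ndarray,
    seed: int,
    max_iter: int = 300,
    kind: str = "node",
) -> tuple[Partition, bool]:
    """PAM-style k-medoids on a precomputed distance matrix (1 - S).

    Alternates nearest-medoid assignment and medoid update (the cluster
    member minimizing total intra-cluster distance) from a seeded uniform
    sample of K initial medoids; stops when the medoid set stabilizes.
    Returns (partition, converged); on hitting ``max_iter`` the best-so-far
    partition is returned with a logged flag.
    """
    n = len(items)
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=K, replace=False))
    converged = False
    for _ in range(max_iter):
        assign = np.argmin(distance[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(K):
            members = np.where(assign == c)[0]
            if members.size == 0:
                continue
            intra = distance[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[np.argmin(intra)]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            converged = True
            break
        medoids = new_medoids
    if not converged:
        log.warning("k-medoids did not converge within %d iterations", max_iter)
    assign = np.argmin(distance[:, medoids], axis=1)
    return Partition({items[i]: int(assign[i]) for i in range(n)}, kind), converged


def kmedoids_cost(partition: Partition, items: list, distance: np.ndarray) -> float:
    """Total distance of items to their cluster medoid (best medoid choice)."""
    idx = {item: i for i, item in enumerate(items)}
    cost = 0.0
    for members in partition.clusters().values():
        rows = [idx[m] for m in members]
        cost += distance[np.ix_(rows, rows)].sum(axis=0).min()
    return float(cost)


def degree_filter(graph: nx.Graph, min_degree: int = 3):
    """Nodes with degree > min_degree and edges with both endpoints passing.

    Degrees are measured on the unfiltered graph; poorly connected proteins
    are more likely to carry noisy interactions.
    """
    deg = dict(graph.degree())
    nodes = {v for v, d in deg.items() if d > min_degree}
    edges = {
        tuple(sorted(e, key=str)) for e in graph.edges if e[0] in nodes and e[1] in nodes
    }
    return nodes, edges
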