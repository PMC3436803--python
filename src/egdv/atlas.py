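"""Canonical atlas of the 2-5-node graphlets and their automorphism orbits.

A *graphlet* is a small connected induced subgraph of a network.  On 2-5
nodes there are exactly 30 connected simple graphs up to isomorphism.  The
automorphism group of each graphlet partitions its nodes into *node orbits*
(73 across the atlas) and its edges into *edge orbits* (69 across the
atlas, 68 excluding the single edge of the 2-node graphlet).  Two nodes
(edges) share an orbit iff some automorphism maps one onto the other.

Orbits are the coordinates of graphlet degree vectors: a node's node-GDV
counts, per node orbit, how many graphlets touch the node at that orbit,
and likewise for edges and edge orbits.

Because orbit counts are not independent (a triangle through an edge forces
3-paths through it, etc.), each orbit carries a weight

    w_i = 1 - log(o_i) / log(n_orbits)

where o_i is the number of orbits whose graphlet occurs as a subgraph of
orbit i's graphlet with an orbit-j edge (node) landing on the focal edge
(node).  Orbits constrained by few others get weights near 1.

Atlas ordering is pinned so that the conventional anchors hold: graphlet 0
is the single edge, 1 the 3-path, 2 the triangle, 3 the 4-path; edge orbit
0 is the 2-node edge, orbit 1 the 3-path edge, orbit 2 the triangle edge,
orbits 3/4 the outer/middle 4-path edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

MIN_NODES = 2
MAX_NODES = 5

N_GRAPHLETS = 30
N_NODE_ORBITS = 73
N_EDGE_ORBITS = 69  # including orbit 0 (the 2-node graphlet's edge)

Edge = tuple[int, int]


def _norm_edge(a: int, b: int) -> Edge:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Graphlet:
    """One isomorphism class of connected simple graphs on 2-5 nodes."""

    id: int
    n: int
    edges: frozenset[Edge]

    @property
    def m(self) -> int:
        return len(self.edges)

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)

    def automorphisms(self) -> list[tuple[int, ...]]:
        """All node permutations preserving the edge set (n! <= 120)."""
        auts = []
        for perm in permutations(range(self.n)):
            if all(_norm_edge(perm[a], perm[b]) in self.edges for a, b in self.edges):
                auts.append(perm)
        return auts


@dataclass
class OrbitTable:
    """Global orbit ids for every (graphlet, node) and (graphlet, edge)."""

    node_orbits: dict[tuple[int, int], int]
    edge_orbits: dict[tuple[int, Edge], int]
    # representative member per global orbit id
    node_orbit_rep: dict[int, tuple[int, int]] = field(default_factory=dict)
    edge_orbit_rep: dict[int, tuple[int, Edge]] = field(default_factory=dict)

    @property
    def n_node_orbits(self) -> int:
        return len(set(self.node_orbits.values()))

    @property
    def n_edge_orbits(self) -> int:
        return len(set(self.edge_orbits.values()))


@dataclass
class OrbitWeights:
    """Dependency counts o_i and weights w_i for a family of orbits.

    For edge orbits the vector covers orbits 1..68 (index i-1 holds orbit
    i); orbit 0 is excluded from edge-GDVs.  For node orbits it covers all
    73 orbits id-aligned.
    """

    kind: str  # "node" | "edge"
    o: np.ndarray
    w: np.ndarray
    offset: int  # global orbit id of vector position 0

    def weight_of(self, orbit_id: int) -> float:
        return float(self.w[orbit_id - self.offset])


def _canonical_key(n: int, edges: frozenset[Edge]) -> tuple:
    """Isomorphism-invariant sort key: (n, m, degseq desc, max adjacency mask)."""
    pairs = list(combinations(range(n), 2))
    degs = tuple(sorted((sum(1 for e in edges if v in e) for v in range(n)), reverse=True))
    best = -1
    for perm in permutations(range(n)):
        mask = 0
        for i, (a, b) in enumerate(pairs):
            if _norm_edge(perm[a], perm[b]) in edges:
                mask |= 1 << i
        if mask > best:
            best = mask
    return (n, len(edges), degs, best)


def _is_connected(n: int, edges: frozenset[Edge]) -> bool:
    if n == 1:
        return True
    adj: dict[int, set[int]] = {v: set() for v in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


def _enumerate_graphlets() -> list[Graphlet]:
    reps: dict[tuple, frozenset[Edge]] = {}
    for n in range(MIN_NODES, MAX_NODES + 1):
        pairs = list(combinations(range(n), 2))
        for mask in range(1, 1 << len(pairs)):
            edges = frozenset(pairs[i] for i in range(len(pairs)) if mask >> i & 1)
            # skip graphs leaving node n-1 isolated (they duplicate smaller n)
            if any(v not in {x for e in edges for x in e} for v in range(n)):
                continue
            if not _is_connected(n, edges):
                continue
            key = _canonical_key(n, edges)
            reps.setdefault(key, edges)
    ordered = sorted(reps.items(), key=lambda kv: kv[0])
    return [Graphlet(i, key[0], edges) for i, (key, edges) in enumerate(ordered)]


def _orbit_partition(members, auts, apply):
    """Partition `members` under the automorphisms, via `apply(aut, member)`."""
    remaining = list(members)
    orbits = []
    while remaining:
        seed = remaining[0]
        orbit = {apply(aut, seed) for aut in auts}
        orbits.append(sorted(orbit))
        remaining = [m for m in remaining if m not in orbit]
    return orbits


@lru_cache(maxsize=1)
def build_atlas() -> tuple[tuple[Graphlet, ...], OrbitTable]:
    """Enumerate the 30 graphlets and number their 73 node / 69 edge orbits.

    Orbits are numbered in graphlet order; within a graphlet, orbits are
    sorted by the (sorted) degree profile of their members, then by their
    smallest member, which fixes the conventional low-order anchors.
    """
    graphlets = _enumerate_graphlets()
    node_orbits: dict[tuple[int, int], int] = {}
    edge_orbits: dict[tuple[int, Edge], int] = {}
    node_rep: dict[int, tuple[int, int]] = {}
    edge_rep: dict[int, tuple[int, Edge]] = {}
    next_node = 0
    next_edge = 0
    for g in graphlets:
        auts = g.automorphisms()
        n_orbs = _orbit_partition(range(g.n), auts, lambda aut, v: aut[v])
        n_orbs.sort(key=lambda orb: (g.degree(orb[0]), orb[0]))
        for orb in n_orbs:
            node_rep[next_node] = (g.id, orb[0])
            for v in orb:
                node_orbits[(g.id, v)] = next_node
            next_node += 1
        e_orbs = _orbit_partition(
            sorted(g.edges), auts, lambda aut, e: _norm_edge(aut[e[0]], aut[e[1]])
        )
        e_orbs.sort(
            key=lambda orb: (tuple(sorted((g.degree(orb[0][0]), g.degree(orb[0][1])))), orb[0])
        )
        for orb in e_orbs:
            edge_rep[next_edge] = (g.id, orb[0])
            for e in orb:
                edge_orbits[(g.id, e)] = next_edge
            next_edge += 1
    table = OrbitTable(node_orbits, edge_orbits, node_rep, edge_rep)
    return tuple(graphlets), table


def _occurs_through_focal(
    host: Graphlet,
    host_focal: tuple,
    pattern: Graphlet,
    pattern_focal: tuple,
    focal_is_edge: bool,
) -> bool:
    """Does `pattern` occur as an induced subgraph of `host` under an
    injection carrying `pattern_focal` onto `host_focal`?

    Induced occurrence (edges and non-edges both preserved) is the sense in
    which one orbit's count constrains another's: every induced pattern
    through the focal element is itself counted at its own orbit.
    """
    if pattern.n > host.n or pattern.m > host.m:
        return False
    host_edges = host.edges
    if focal_is_edge:
        px, py = pattern_focal
        hx, hy = host_focal
        seeds = [{px: hx, py: hy}, {px: hy, py: hx}]
    else:
        seeds = [{pattern_focal: host_focal}]
    pairs = list(combinations(range(pattern.n), 2))
    for seed in seeds:
        free_p = [v for v in range(pattern.n) if v not in seed]
        free_h = [v for v in range(host.n) if v not in seed.values()]
        for image in permutations(free_h, len(free_p)):
            f = dict(seed)
            f.update(zip(free_p, image))
            if all(
                ((a, b) in pattern.edges) == (_norm_edge(f[a], f[b]) in host_edges)
                for a, b in pairs
            ):
                return True
    return False


@lru_cache(maxsize=1)
def edge_orbit_dependency_sets() -> dict[int, frozenset[int]]:
    """Orbit i -> the edge orbits j (1..68, including i) that affect it.

    Orbit j affects orbit i when orbit j's graphlet occurs as a (not
    necessarily induced) subgraph of orbit i's graphlet under a mapping
    that carries an orbit-j edge onto the focal edge of orbit i.
    """
    graphlets, table = build_atlas()
    deps: dict[int, frozenset[int]] = {}
    for i in range(1, N_EDGE_ORBITS):
        gi, ei = table.edge_orbit_rep[i]
        deps[i] = frozenset(
            j
            for j in range(1, N_EDGE_ORBITS)
            if _occurs_through_focal(
                graphlets[gi], ei, graphlets[table.edge_orbit_rep[j][0]],
                table.edge_orbit_rep[j][1], True,
            )
        )
    return deps


@lru_cache(maxsize=1)
def edge_orbit_dependencies() -> OrbitWeights:
    """o_i and w_i for edge orbits 1..68.

    o_i counts the edge orbits j (including i itself) whose graphlet occurs
    as a subgraph of orbit i's graphlet with an orbit-j edge on the focal
    edge; w_i = 1 - log(o_i)/log(68).
    """
    n = N_EDGE_ORBITS - 1
    deps = edge_orbit_dependency_sets()
    o = np.array([len(deps[i]) for i in range(1, N_EDGE_ORBITS)], dtype=int)
    w = 1.0 - np.log(o) / math.log(n)
    return OrbitWeights("edge", o, w, offset=1)


@lru_cache(maxsize=1)
def node_orbit_dependencies() -> OrbitWeights:
    """o_i and w_i for all 73 node orbits, normalized by log(73)."""
    graphlets, table = build_atlas()
    o = np.zeros(N_NODE_ORBITS, dtype=int)
    for i in range(N_NODE_ORBITS):
        gi, vi = table.node_orbit_rep[i]
        for j in range(N_NODE_ORBITS):
            gj, vj = table.node_orbit_rep[j]
            if _occurs_through_focal(graphlets[gi], vi, graphlets[gj], vj, False):
                o[i] += 1
    w = 1.0 - np.log(o) / math.log(N_NODE_ORBITS)
    return OrbitWeights("node", o, w, offset=0)


def atlas_table():
    """Reference table of every orbit: kind, id, graphlet, members, o_i, w_i.

    Returns a pandas DataFrame (one row per orbit) suitable for TSV export.
    """
    import pandas as pd

    graphlets, table = build_atlas()
    ew = edge_orbit_dependencies()
    nw = node_orbit_dependencies()
    rows = []
    for oid in range(N_NODE_ORBITS):
        gid, _ = table.node_orbit_rep[oid]
        members = sorted(v for (g, v), o in table.node_orbits.items() if g == gid and o == oid)
        rows.append(
            {
                "kind": "node",
                "orbit": oid,
                "graphlet": gid,
                "members": ",".join(map(str, members)),
                "o": int(nw.o[oid]),
                "w": float(nw.w[oid]),
            }
        )
    for oid in range(N_EDGE_ORBITS):
        gid, _ = table.edge_orbit_rep[oid]
        members = sorted(e for (g, e), o in table.edge_orbits.items() if g == gid and o == oid)
        rows.append(
            {
                "kind": "edge",
                "orbit": oid,
                "graphlet": gid,
                "members": ";".join(f"{a}-{b}" for a, b in members),
                "o": int(ew.o[oid - 1]) if oid >= 1 else 1,
                "w": float(ew.w[oid - 1]) if oid >= 1 else 1.0,
            }
        )
    return pd.DataFrame(rows)
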