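"""Seeded synthetic networks, annotations and pathogen maps for testing.

These generators emulate only the statistical structure the method
exploits: topologically coherent groups of edges (planted-partition
blocks), annotation terms concentrated within groups, and pathogens whose
interactors concentrate within groups.  They make no attempt to model PPI
degree distributions or assay-specific noise.

Everything is deterministic given its seed; regenerating a fixture with
the same parameters yields byte-identical TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import PathogenMap


def _label(i: int) -> str:
    return f"n{i:03d}"


def toy_graph(name: str, size: int = 5) -> nx.Graph:
    """Named toy graphs: edge, path-3, path-4, triangle, clique, star."""
    if name == "edge":
        g = nx.path_graph(2)
    elif name == "path-3":
        g = nx.path_graph(3)
    elif name == "path-4":
        g = nx.path_graph(4)
    elif name == "triangle":
        g = nx.complete_graph(3)
    elif name == "clique":
        g = nx.complete_graph(size)
    elif name == "star":
        g = nx.star_graph(size)
    else:
        raise ValueError(f"unknown toy graph {name!r}")
    return nx.relabel_nodes(g, {i: _label(i) for i in g.nodes})


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi G(n, p) with string node labels."""
    if not 0 <= p <= 1 or n < 1:
        raise ValueError("need n >= 1 and p in [0, 1]")
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: _label(i) for i in g.nodes})


def planted_partition(
    blocks: int, block_size: int, p_in: float, p_out: float, seed: int
):
    """Planted-partition graph and its ground-truth block labels.

    Within-block edge probability p_in should dominate p_out so that the
    blocks form recoverable edge communities.
    """
    if blocks < 1 or block_size < 1:
        raise ValueError("blocks and block_size must be >= 1")
    g = nx.planted_partition_graph(blocks, block_size, p_in, p_out, seed=seed)
    mapping = {i: _label(i) for i in g.nodes}
    truth = {_label(i): i // block_size for i in g.nodes}
    g = nx.relabel_nodes(nx.Graph(g), mapping)
    return g, truth


def make_annotations(
    blocks: dict, purity: float, seed: int, n_terms: int | None = None,
    extra_term_rate: float = 0.3,
) -> dict:
    """Block-concentrated annotation terms.

    Each block has a dominant term; each node receives its block's dominant
    term with probability ``purity`` and a uniformly random other term
    otherwise, plus Poisson(``extra_term_rate``) extra random terms so that
    per-node term counts vary (needed for a non-degenerate OQ).
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    block_ids = sorted(set(blocks.values()))
    if n_terms is None:
        n_terms = len(block_ids)
    terms = [f"T{i}" for i in range(n_terms)]
    dominant = {b: terms[i % n_terms] for i, b in enumerate(block_ids)}
    out: dict = {}
    for v in sorted(blocks, key=str):
        dom = dominant[blocks[v]]
        if rng.random() < purity or n_terms == 1:
            chosen = dom
        else:
            others = [t for t in terms if t != dom]
            chosen = others[rng.integers(len(others))]
        mine = {chosen}
        for _ in range(rng.poisson(extra_term_rate)):
            mine.add(terms[rng.integers(n_terms)])
        out[v] = mine
    return out


def make_pathogen_map(
    blocks: dict,
    n_pathogens: int,
    within_fraction: float,
    seed: int,
    interactors_per_pathogen: int = 6,
) -> PathogenMap:
    """Pathogens whose interactors concentrate within one block each.

    Pathogen j is homed at block j mod n_blocks and draws
    ``interactors_per_pathogen`` interactors, a ``within_fraction`` share
    from its home block and the rest uniformly from other blocks.  Every
    pathogen gets at least two interactors.
    """
    if not 0 <= within_fraction <= 1:
        raise ValueError("within_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    block_ids = sorted(set(blocks.values()))
    by_block = {b: sorted(v for v in blocks if blocks[v] == b) for b in block_ids}
    pairs = []
    size = max(2, interactors_per_pathogen)
    for j in range(n_pathogens):
        home = block_ids[j % len(block_ids)]
        n_within = max(2, int(round(within_fraction * size)))
        n_within = min(n_within, len(by_block[home]), size)
        chosen = list(rng.choice(by_block[home], size=n_within, replace=False))
        others = sorted(v for b in block_ids if b != home for v in by_block[b])
        n_out = min(size - n_within, len(others))
        if n_out > 0 and within_fraction < 1:
            chosen += list(rng.choice(others, size=n_out, replace=False))
        pairs += [(v, f"P{j}") for v in chosen]
    return PathogenMap.from_pairs(pairs)


@dataclass
class FixtureSpec:
    """Full description of a synthetic study: graph + annotations + pathogens."""

    blocks: int = 4
    block_size: int = 8
    p_in: float = 0.8
    p_out: float = 0.02
    purity: float = 1.0
    n_pathogens: int = 4
    within_fraction: float = 1.0
    interactors_per_pathogen: int = 6
    seed: int = 0

    def build(self):
        g, truth = planted_partition(
            self.blocks, self.block_size, self.p_in, self.p_out, self.seed
        )
        ann = make_annotations(truth, self.purity, self.seed + 1)
        pmap = make_pathogen_map(
            truth,
            self.n_pathogens,
            self.within_fraction,
            self.seed + 2,
            self.interactors_per_pathogen,
        )
        return g, truth, ann, pmap


def write_fixture_dir(spec: FixtureSpec, out_dir) -> dict:
    """Write edges.tsv, annotations.tsv, pathogens.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, truth, ann, pmap = spec.build()
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in g.edges))
    edges.to_csv(out / "edges.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        sorted((v, t) for v, terms in ann.items() for t in terms)
    ).to_csv(out / "annotations.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(sorted(pmap.associations)).to_csv(
        out / "pathogens.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame(sorted(truth.items())).to_csv(
        out / "truth.tsv", sep="\t", header=False, index=False
    )
    return {"edges": g.number_of_edges(), "nodes": g.number_of_nodes()}
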