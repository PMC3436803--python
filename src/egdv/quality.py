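"""Partition-quality measures: CC, OC, CQ, OQ and the normalized overall score.

Given a partition's node clusters (possibly overlapping, when induced from
an edge partition) and per-node annotation term sets:

* CC (cluster coverage) — fraction of the node universe in at least one
  non-trivial cluster (>= 3 distinct nodes);
* OC (overlap coverage) — mean number of non-trivial clusters per node;
* CQ (cluster quality) — mean pairwise annotation similarity over
  intra-cluster annotated pairs divided by the mean over all annotated
  pairs in the network (default pairwise similarity: Jaccard of term sets;
  injectable);
* OQ (overlap quality) — plug-in mutual information, in bits, between a
  node's annotation-term count and its non-trivial-cluster count.

To compare methods, each raw measure is divided by its maximum across the
compared methods (so the best method scores 1) and the four normalized
values are summed: the overall quality is at most 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from sklearn.metrics import mutual_info_score


@dataclass
class QualityReport:
    cc: float
    oc: float
    cq: float | None  # None when no annotated intra-cluster pair exists
    oq: float
    normalized: dict = field(default_factory=dict)
    overall: float | None = None


def _nontrivial(clusters: dict[int, set]) -> dict[int, set]:
    return {cid: nodes for cid, nodes in clusters.items() if len(nodes) >= 3}


def cluster_coverage(clusters: dict[int, set], node_universe: set) -> float:
    if not node_universe:
        raise ValueError("empty node universe")
    covered = set().union(*_nontrivial(clusters).values()) if _nontrivial(clusters) else set()
    return len(covered & node_universe) / len(node_universe)


def overlap_coverage(clusters: dict[int, set], node_universe: set) -> float:
    if not node_universe:
        raise ValueError("empty node universe")
    nt = _nontrivial(clusters)
    total = sum(sum(1 for nodes in nt.values() if v in nodes) for v in node_universe)
    return total / len(node_universe)


def jaccard(terms_a: set, terms_b: set) -> float:
    union = terms_a | terms_b
    if not union:
        return 0.0
    return len(terms_a & terms_b) / len(union)


def cluster_quality(
    clusters: dict[int, set],
    annotations: dict,
    node_universe: set | None = None,
    pair_similarity=jaccard,
) -> float | None:
    """Ratio of mean intra-cluster pair similarity to the network-wide mean.

    Pairs are counted once per shared cluster membership; both means run
    over annotated nodes only (unannotated pairs have undefined
    similarity).  Returns None when undefined.
    """
    annotated = {v for v, terms in annotations.items() if terms}
    if node_universe is not None:
        annotated &= node_universe
    intra_sum = 0.0
    intra_n = 0
    for nodes in clusters.values():
        members = sorted(nodes & annotated, key=str)
        for a, b in combinations(members, 2):
            intra_sum += pair_similarity(annotations[a], annotations[b])
            intra_n += 1
    all_nodes = sorted(annotated, key=str)
    all_sum = 0.0
    all_n = 0
    for a, b in combinations(all_nodes, 2):
        all_sum += pair_similarity(annotations[a], annotations[b])
        all_n += 1
    if intra_n == 0 or all_n == 0 or all_sum == 0:
        return None
    return (intra_sum / intra_n) / (all_sum / all_n)


def overlap_quality(clusters: dict[int, set], annotations: dict, node_universe: set) -> float:
    """Mutual information (bits) between term counts and cluster counts."""
    if not node_universe:
        raise ValueError("empty node universe")
    nt = _nontrivial(clusters)
    nodes = sorted(node_universe, key=str)
    x = [len(annotations.get(v, ())) for v in nodes]
    y = [sum(1 for members in nt.values() if v in members) for v in nodes]
    return float(mutual_info_score(x, y)) / math.log(2)


def quality_report(
    clusters: dict[int, set],
    node_universe: set,
    annotations: dict,
    pair_similarity=jaccard,
) -> QualityReport:
    return QualityReport(
        cc=cluster_coverage(clusters, node_universe),
        oc=overlap_coverage(clusters, node_universe),
        cq=cluster_quality(clusters, annotations, node_universe, pair_similarity),
        oq=overlap_quality(clusters, annotations, node_universe),
    )


def normalize_and_score(reports: dict) -> dict:
    """Normalize each measure by its max across methods and sum into overall.

    The best method per measure gets 1; a measure whose maximum is 0 (or
    undefined everywhere) contributes 0 to every method.  Mutates and
    returns the reports with ``normalized`` and ``overall`` filled in.
    """
    if len(reports) < 2:
        raise ValueError("need at least two methods to normalize")
    measures = ["cc", "oc", "cq", "oq"]
    for m in measures:
        vals = {k: getattr(r, m) for k, r in reports.items()}
        mx = max((v for v in vals.values() if v is not None), default=0.0)
        for k, r in reports.items():
            v = vals[k]
            r.normalized[m] = 0.0 if (v is None or mx == 0) else v / mx
    for r in reports.values():
        r.overall = sum(r.normalized[m] for m in measures)
    return reports
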