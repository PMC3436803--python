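"""Hypergeometric cluster enrichment and pathogen-interacting protein prediction.

A host protein is *pathogen-interacting* (PI) if it has a known physical
interaction with a pathogen.  The working hypothesis: if a cluster is
significantly enriched in proteins interacting with some pathogen, its
remaining members are candidate interactors of that pathogen.

Enrichment of a cluster for a pathogen is p/C, where C is the number of
eligible PI proteins in the cluster and p of them interact with the
pathogen.  Significance is the hypergeometric upper tail P(X >= p) with
population N (all eligible PI proteins), P successes (the pathogen's
interactors) and C draws; raw p < alpha (default 0.05) is significant, per
the original protocol no multiple-testing correction is applied.

Prediction accuracy is evaluated by leave-one-out cross-validation: each
known (protein, pathogen) association is hidden in turn, enrichment and
significance are recomputed on the remaining data, and the protein is
predicted as interacting when its cluster is significant with enrichment
above a threshold k swept from 0% to 100% in 1% steps.  Precision, recall
and F-score are tallied per k, against a size-preserving random-cluster
baseline averaged over seeded randomization runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class PathogenMap:
    """Known (protein, pathogen) associations with derived lookups."""

    associations: frozenset

    def __post_init__(self):
        p2p: dict = {}
        byp: dict = {}
        for prot, path in self.associations:
            p2p.setdefault(prot, set()).add(path)
            byp.setdefault(path, set()).add(prot)
        self.protein_to_pathogens = p2p
        self.pathogen_to_proteins = byp

    @classmethod
    def from_pairs(cls, pairs) -> "PathogenMap":
        return cls(frozenset((str(a), str(b)) for a, b in pairs))


@dataclass
class EnrichmentRecord:
    cluster: int
    pathogen: str
    N: int
    P: int
    C: int
    p: int
    enrichment: float
    p_value: float


@dataclass
class PRCurve:
    """Precision/recall/F-score per enrichment threshold k = 0..100 (%)."""

    k: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    n_predictions: np.ndarray
    n_known: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "precision": self.precision,
                "recall": self.recall,
                "f_score": self.f_score,
                "n_predictions": self.n_predictions,
            }
        )

    def at(self, k: int) -> dict:
        i = int(k)
        return {
            "k": i,
            "precision": float(self.precision[i]),
            "recall": float(self.recall[i]),
            "f_score": float(self.f_score[i]),
        }


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def eligible_universe(graph: nx.Graph, pathogen_map: PathogenMap, min_degree: int = 3):
    """Eligible PI universe N and the filtered pathogen map.

    A pathogen is kept only if it interacts with at least two network
    proteins of degree > min_degree (a single-interactor pathogen can never
    be predicted for other proteins and would only depress recall); N is
    the set of proteins interacting with at least one kept pathogen.
    Degrees come from the unfiltered graph.
    """
    deg = dict(graph.degree())
    high = {v for v, d in deg.items() if d > min_degree}
    kept_paths = {
        path
        for path, prots in pathogen_map.pathogen_to_proteins.items()
        if len(prots & high) >= 2
    }
    filtered = frozenset(
        (prot, path)
        for prot, path in pathogen_map.associations
        if path in kept_paths and prot in high
    )
    universe = {prot for prot, _ in filtered}
    if not universe:
        raise ValueError(
            f"no eligible PI proteins: {len(high)} nodes pass degree>{min_degree}, "
            f"{len(kept_paths)} pathogens have >=2 eligible interactors"
        )
    return universe, PathogenMap(filtered)


def hypergeom_pvalue(N: int, P: int, C: int, p: int) -> float:
    """Upper tail P(X >= p), X ~ Hypergeom(population N, successes P, draws C)."""
    if not (0 <= p <= min(P, C) <= N) or P > N or C > N:
        raise ValueError(f"inconsistent counts N={N} P={P} C={C} p={p}")
    return float(hypergeom.sf(p - 1, N, P, C))


def enrichment_table(
    clusters: dict[int, set], pathogen_map: PathogenMap, universe: set
) -> list[EnrichmentRecord]:
    """Enrichment and significance of every (cluster, pathogen) pair with p >= 1."""
    N = len(universe)
    records = []
    for cid, members in sorted(clusters.items()):
        c_set = members & universe
        C = len(c_set)
        if C == 0:
            continue
        for path in sorted(pathogen_map.pathogen_to_proteins):
            interactors = pathogen_map.pathogen_to_proteins[path] & universe
            P = len(interactors)
            p = len(c_set & interactors)
            if p == 0:
                continue
            records.append(
                EnrichmentRecord(
                    cid, path, N, P, C, p, p / C, hypergeom_pvalue(N, P, C, p)
                )
            )
    return records


def _prediction_scores(
    clusters: dict[int, set],
    pathogen_map: PathogenMap,
    universe: set,
    alpha: float,
    recompute_significance: bool = True,
):
    """Best significant leave-one-out enrichment per (protein, pathogen) pair.

    Hiding an association removes it from both the cluster count p and the
    pathogen total P; the protein itself stays in the cluster (N and C are
    unchanged).  Pairs whose best cluster is not significant get no score.
    """
    N = len(universe)
    scores: dict = {}
    known: set = set()
    for cid, members in clusters.items():
        c_set = members & universe
        C = len(c_set)
        if C == 0:
            continue
        for path, all_interactors in pathogen_map.pathogen_to_proteins.items():
            interactors = all_interactors & universe
            P = len(interactors)
            p = len(c_set & interactors)
            # score for members not associated with this pathogen
            if p >= 1:
                sig_non = hypergeom_pvalue(N, P, C, p) < alpha
                e_non = p / C
            else:
                sig_non, e_non = False, 0.0
            # score for associated members, with their association hidden
            if p >= 2:
                if recompute_significance:
                    sig_hid = hypergeom_pvalue(N, P - 1, C, p - 1) < alpha
                else:
                    sig_hid = hypergeom_pvalue(N, P, C, p) < alpha
                e_hid = (p - 1) / C
            else:
                sig_hid, e_hid = False, 0.0
            for v in members:
                assoc = path in pathogen_map.protein_to_pathogens.get(v, ())
                if assoc:
                    known.add((v, path))
                    sig, e = sig_hid, e_hid
                else:
                    sig, e = sig_non, e_non
                if sig:
                    key = (v, path)
                    if e > scores.get(key, -1.0):
                        scores[key] = e
    return scores, known


def loocv_pr_curve(
    clusters: dict[int, set],
    pathogen_map: PathogenMap,
    universe: set,
    alpha: float = 0.05,
    recompute_significance: bool = True,
) -> PRCurve:
    """Leave-one-out precision/recall/F over the k = 0..100% threshold sweep.

    At each k a (protein, pathogen) pair is predicted iff some cluster
    containing the protein is significantly enriched for the pathogen with
    (leave-one-out) enrichment strictly above k.  TP + FN equals the number
    of known associations of clustered proteins at every k.
    """
    if not universe:
        raise ValueError("empty universe")
    scores, known = _prediction_scores(
        clusters, pathogen_map, universe, alpha, recompute_significance
    )
    ks = np.arange(101)
    known_scores = np.array([scores.get(pair, -1.0) for pair in known], dtype=float)
    new_scores = np.array(
        [s for pair, s in scores.items() if pair not in known], dtype=float
    )
    precision = np.zeros(101)
    recall = np.zeros(101)
    f = np.zeros(101)
    npred = np.zeros(101, dtype=int)
    n_known = len(known)
    for k in ks:
        thr = k / 100.0
        tp = int((known_scores > thr).sum())
        fp = int((new_scores > thr).sum())
        npred[k] = tp + fp
        precision[k] = tp / (tp + fp) if tp + fp else 0.0
        recall[k] = tp / n_known if n_known else 0.0
        f[k] = f_score(precision[k], recall[k])
    return PRCurve(ks, precision, recall, f, npred, n_known)


def random_baseline(
    clusters: dict[int, set],
    pathogen_map: PathogenMap,
    universe: set,
    runs: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    pool: set | None = None,
) -> PRCurve:
    """Mean PR curve over size-preserving random cluster assignments.

    Each run redraws every cluster as a uniform sample (without
    replacement, per cluster) of the same size from the pool of clustered
    nodes, then scores it with the same LOOCV procedure.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rng = np.random.default_rng(seed)
    if pool is None:
        pool = set().union(*clusters.values()) if clusters else set()
    pool_list = sorted(pool, key=str)
    sizes = {cid: len(members) for cid, members in clusters.items()}
    acc_p = np.zeros(101)
    acc_r = np.zeros(101)
    acc_f = np.zeros(101)
    acc_n = np.zeros(101)
    n_known = 0
    for _ in range(runs):
        rand_clusters = {
            cid: set(rng.choice(pool_list, size=min(sz, len(pool_list)), replace=False))
            for cid, sz in sizes.items()
        }
        curve = loocv_pr_curve(rand_clusters, pathogen_map, universe, alpha)
        acc_p += curve.precision
        acc_r += curve.recall
        acc_f += curve.f_score
        acc_n += curve.n_predictions
        n_known = curve.n_known
    return PRCurve(
        np.arange(101), acc_p / runs, acc_r / runs, acc_f / runs, acc_n / runs, n_known
    )


@dataclass
class Prediction:
    protein: str
    pathogen: str
    clusters: list
    enrichment: float
    p_value: float
    methods: list = field(default_factory=list)


def predict_new(
    clusters: dict[int, set],
    pathogen_map: PathogenMap,
    universe: set,
    k: float = 66.0,
    alpha: float = 0.05,
    method: str | None = None,
) -> list[Prediction]:
    """New (protein, pathogen) predictions at enrichment threshold k (%).

    For every significantly enriched (cluster, pathogen) with enrichment
    strictly above k, every cluster member not already associated with the
    pathogen is predicted; duplicates across clusters are merged keeping
    the best-supported record.
    """
    out: dict = {}
    for rec in enrichment_table(clusters, pathogen_map, universe):
        if rec.p_value >= alpha or rec.enrichment <= k / 100.0:
            continue
        for v in clusters[rec.cluster]:
            if rec.pathogen in pathogen_map.protein_to_pathogens.get(v, ()):
                continue
            key = (v, rec.pathogen)
            prev = out.get(key)
            if prev is None:
                out[key] = Prediction(
                    v,
                    rec.pathogen,
                    [rec.cluster],
                    rec.enrichment,
                    rec.p_value,
                    [method] if method else [],
                )
            else:
                prev.clusters.append(rec.cluster)
                if rec.enrichment > prev.enrichment:
                    prev.enrichment = rec.enrichment
                    prev.p_value = rec.p_value
    return sorted(out.values(), key=lambda r: (r.protein, r.pathogen))


def merge_predictions(per_method: dict[str, list]) -> list[Prediction]:
    """Union of per-method predictions annotated with supporting methods."""
    merged: dict = {}
    for method, preds in per_method.items():
        for pred in preds:
            key = (pred.protein, pred.pathogen)
            if key not in merged:
                merged[key] = Prediction(
                    pred.protein,
                    pred.pathogen,
                    list(pred.clusters),
                    pred.enrichment,
                    pred.p_value,
                    [method],
                )
            else:
                cur = merged[key]
                cur.methods.append(method)
                if pred.enrichment > cur.enrichment:
                    cur.enrichment = pred.enrichment
                    cur.p_value = pred.p_value
    return sorted(merged.values(), key=lambda r: (r.protein, r.pathogen))
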