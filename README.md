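# egdv — graphlet-based edge clustering for protein interaction networks

`egdv` clusters the **edges** of a protein–protein interaction (PPI)
network by the topological similarity of their extended neighborhoods, and
uses the clusters to predict **pathogen-interacting (PI) proteins** —
human proteins that physically bind a pathogen protein and are therefore
drug-target candidates.

Why edges? Proteins belong to multiple functional groups, and a disjoint
partition of *nodes* cannot express that overlap — but a partition of
*edges* can: a node inherits membership in the cluster of each of its
edges. Earlier edge clustering grouped only *adjacent* edges by shared
neighborhoods; most protein pairs interacting with the same pathogen are
*not* adjacent in the network, so a similarity that works for arbitrary
edge pairs is needed.

## The measure

A *graphlet* is a small connected induced subgraph; on 2–5 nodes there are
30 of them, whose automorphism groups define 73 node orbits and 69 edge
orbits (68 excluding the trivial single-edge orbit). The **edge graphlet
degree vector** (edge-GDV) of an edge counts, for each edge orbit *i*, the
graphlets touching the edge at that orbit. Two edge-GDVs *e*, *f* are
compared orbit-wise,

```
D_i(e, f) = w_i · |log(e_i + 1) − log(f_i + 1)| / log(max(e_i, f_i) + 2)
D(e, f)   = Σ_i D_i / Σ_i w_i          S(e, f) = 1 − D(e, f) ∈ (0, 1]
```

where the weight `w_i = 1 − log(o_i)/log(68)` discounts orbits constrained
by many others (`o_i` counts the orbits whose graphlet occurs, induced,
through the focal edge of orbit *i*). Node-GDV-similarity is the analogous
measure on the 73 node orbits. The package also implements the
shared-neighborhood measure **edge-SN** (Jaccard of the non-shared
endpoints' inclusive neighborhoods) for comparison.

On top of the similarity sit: single-linkage hierarchical clustering with
dendrogram cutting and partition-density-based level selection, seeded
k-medoids, the four partition-quality measures (cluster coverage, overlap
coverage, cluster quality, overlap quality) with cross-method
normalization, and hypergeometric cluster-enrichment prediction of PI
proteins with a leave-one-out precision/recall/F sweep over the enrichment
threshold and a size-preserving random-cluster baseline.

## Worked example

Generate a synthetic network of four planted communities (8 nodes each,
within-block edge probability 0.8), with four pathogens whose interactors
each sit inside one block, then run the edge hierarchical-clustering
pipeline:

```sh
egdv simulate --seed 42 --out-dir demo/
egdv run --graph demo/edges.tsv --pathogens demo/pathogens.tsv \
         --annotations demo/annotations.tsv --strategy edge-hie \
         --out-dir demo/out --seed 1
```

With `K_hie = 4` and adjacent-only similarity the run prints (abridged):

```json
{
  "K": 4,
  "n_nodes": 32, "n_edges": 100, "n_items_clustered": 100,
  "partition_density": 0.458,
  "quality": {"cc": 1.0, "oc": 1.09, "cq": 1.97, "oq": 0.030},
  "n_pi_proteins": 24, "n_pathogens": 4,
  "pr_at_k": {"k": 66, "precision": 0.706, "recall": 0.5, "f_score": 0.585},
  "random_f_at_k": 0.0,
  "n_predictions": 5
}
```

Reading: the 100 edges were cut into 4 clusters whose partition density is
0.458; every node lands in a non-trivial cluster (`cc = 1.0`) and
intra-cluster annotation similarity is ~2× the network background
(`cq = 1.97`). In leave-one-out cross-validation at enrichment threshold
k = 66%, half of the known protein–pathogen associations are recovered at
precision 0.706 (F = 0.585), while size-matched random clusters score
F = 0 — the planted PI modules are real signal, not cluster-size artifact.
Five new protein–pathogen associations are predicted at this threshold.

Every stage is also exposed separately (`egdv atlas | gdv | similarity |
cluster | quality | enrich | baseline | predict`); run `egdv --help`.

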