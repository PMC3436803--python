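# Methods

## Graphlet atlas and orbits

The atlas enumerates every connected simple graph on 2–5 nodes up to
isomorphism (30 graphlets) by scanning all labelled adjacency masks per
node count and keeping one representative per canonical key. The key is
`(n, m, degree sequence descending, maximal adjacency bitmask over all
permutations)`; sorting by it pins the conventional anchors — graphlet 0
is the single edge, 1 the 3-node path, 2 the triangle, 3 the 4-node path —
without special-casing (the path's descending degree sequence (2,2,1,1)
precedes the claw's (3,1,1,1)).

Automorphism groups are computed by exhaustive permutation (≤ 5! = 120 per
graphlet), which is trivially correct at this size. Node orbits and edge
orbits are the automorphism equivalence classes; globally there are 73
node orbits and 69 edge orbits (68 on the 3–5-node graphlets). Within a
graphlet, orbits are numbered by the sorted degree profile of their
members, then by smallest member, which reproduces the conventional
low-order edge-orbit numbering (3-path edge = 1, triangle = 2, 4-path
outer/middle = 3/4). All similarity values are invariant to the numbering;
only the anchors are observable.

### Orbit dependency weights

Orbit counts are not independent: every graphlet induced through an edge
contributes to exactly one orbit count of that edge, so a count difference
at one orbit forces differences at orbits whose graphlets contain it. We
formalize "orbit j affects orbit i" as: orbit j's graphlet occurs as an
**induced** subgraph of orbit i's graphlet under an injection carrying an
orbit-j edge (node) onto the focal edge (node) of orbit i. The induced
reading — rather than arbitrary subgraph containment — is what makes the
dependency counts meaningful: induced occurrences are themselves counted
at their own orbit. It also keeps every weight strictly positive (the
complete-graph orbits would otherwise be "affected" by all orbits and get
weight exactly 0, outside the documented (0, 1] range) and reproduces the
classical node-orbit dependency counts (1 for the degree orbit, 2 for the
triangle node, 3 for the K4 node, 4 for the K5 node). The weight is
`w_i = 1 − log(o_i)/log(68)` for the 68 edge orbits and
`log(73)` normalization for the 73 node orbits. Edge-orbit dependencies
range over orbits 1–68 only, since orbit 0 (the edge itself) is excluded
from edge-GDVs; consequently `o = 1` and `w = 1` are attainable (the
3-path and triangle edge orbits).

## GDV counting

Counting enumerates each connected induced subgraph on 2–5 nodes exactly
once via ESU-style extension (grow from each root using only higher-indexed
vertices, extending with exclusive neighbors) and classifies it in O(1)
through a lookup table precomputed per subgraph size, keyed by the
labelled adjacency bitmask and storing the global orbit id of every node
and edge position. Table construction brute-forces one isomorphism per
labelled mask (≤ 1024 masks × ≤ 120 permutations at n = 5) and is cached
per process. Node-GDVs include the size-2 subgraphs (element 0 is the
degree); edge-GDVs cover sizes 3–5 (orbits 1–68).

Correctness is pinned in the tests to an independent oracle that iterates
every node subset, checks induced connectivity, and classifies by
exhaustive isomorphism — plus conservation laws (degree sum = 2|E|;
triangle-orbit edge counts = 3 × triangle count) and isomorphism
invariance.

GDVs are always computed on the full input graph; the degree filter
(keep nodes with degree > 3 and edges whose both endpoints pass, degrees
measured unfiltered) applies only to which items enter clustering and the
downstream analyses.

## Similarity

The total GDV distance is `D = Σ_i D_i / Σ_i w_i` with the per-orbit
`D_i` of the README; the normalization by `Σ w_i` guarantees `D < 1`
(each `D_i < w_i` strictly, because of the +1/+2 constants), hence
`S = 1 − D ∈ (0, 1]` with equality exactly for identical vectors. Natural
logs are used; the base cancels in `D_i`.

Two pairwise scopes are exposed for edge similarity: *unrestricted*
(any edge pair — the measure's distinguishing capability) and
*adjacent-only*, where non-adjacent pairs are assigned similarity 0, the
minimum, reproducing adjacent-edge-only clustering. edge-SN is defined for
adjacent pairs only and is likewise 0 elsewhere in matrix form.

## Clustering

**Single linkage** is implemented as maximum-spanning-tree agglomeration
(Kruskal order on descending similarity), which is exactly single-linkage
with inter-cluster similarity = best cross pair. Ties are broken by
lexicographic item ids, making the dendrogram deterministic; the
equivalence with SciPy's `linkage(method="single")` and with brute-force
threshold-component clustering is asserted in tests. **Cutting** undoes
merges from the top; a requested K that falls inside a block of tied merge
levels completes the block and returns the nearest achievable K′ ≤ K with
a logged note (treating tied levels as one level keeps cuts well defined).

**Partition density** of an edge partition is
`D = (2/M) Σ_C m_C (m_C − (n_C − 1)) / ((n_C − 2)(n_C − 1))` — the
edge-count-weighted mean of the per-cluster densities
`D_C = [m_C − (n_C−1)] / [n_C(n_C−1)/2 − (n_C−1)]` — with `D_C := 0` for
two-node (single-edge) clusters, where the formula is 0/0 and the cluster
is trivial anyway. M is the number of clustered edges. Level selection
strategies: maximum D; maximum D subject to a cluster-coverage cap; and
best overall quality, where the four quality measures are normalized
across the scanned levels and summed.

**k-medoids** alternates nearest-medoid assignment and medoid update
(cluster member minimizing total intra-cluster distance) on distance
`1 − S`, from a seeded uniform sample of K initial medoids, stopping when
the medoid set stabilizes (default cap 300 iterations; non-convergence
returns best-so-far with a logged flag). Ties in assignment and update go
to the lowest index, so runs are bit-reproducible given the seed. Both
steps are non-increasing in the clustering cost, which the tests verify
along the iteration trajectory.

Defaults mirror the human-network protocol: `min_degree = 3`,
`K_HIE = 1250`, `K_KM = 1000`; on inputs with fewer items K is clamped
with a logged note.

## Partition quality

CC is the fraction of the node universe in ≥ 1 non-trivial (≥ 3-node)
cluster; OC the mean number of non-trivial clusters per node (edge
partitions induce overlapping memberships, so OC can exceed 1); CQ the
ratio of mean pairwise annotation similarity over intra-cluster annotated
pairs (counted once per shared cluster) to the mean over all annotated
pairs — the default pair similarity is the Jaccard index of term sets,
injectable for semantic variants, and the background mean is restricted to
annotated nodes because unannotated pairs have no defined similarity; OQ
is the plug-in mutual information, in bits, between per-node term counts
and non-trivial-cluster counts (raw integer counts, no binning). For
method comparison each measure is divided by its maximum across methods
and the four normalized values are summed (maximum 4); an undefined CQ or
an all-zero measure contributes 0.

## Enrichment and prediction

Eligibility: a pathogen must interact with ≥ 2 network proteins of degree
> 3 (a single-interactor pathogen could never be predicted for other
proteins and would only depress recall); the PI universe N is the set of
proteins interacting with ≥ 1 kept pathogen. The hypergeometric test uses
population N, successes P (the pathogen's interactors in N), draws C (the
cluster's members in N) and observed p, with upper tail P(X ≥ p); raw
p-value < 0.05 is significant — no multiple-testing correction, matching
the original protocol.

LOOCV hides one known association at a time: both the cluster count p and
the pathogen total P are decremented; the protein stays in the cluster, so
N and C are unchanged. Significance is recomputed on the hidden data by
default (`recompute_significance=False` reuses full-data significance).
A pair is predicted at threshold k iff some cluster containing the protein
is significant with enrichment strictly above k; precision/recall/F are
tallied per k ∈ {0, …, 100}%, so TP + FN equals the number of known
associations of clustered proteins at every k, and recall is
non-increasing in k. The baseline redraws every cluster as a uniform
sample of the same size from the pool of clustered nodes and averages the
curves over seeded runs. Final predictions at k = 66% emit every member of
a significantly enriched cluster not already associated with the pathogen;
predictions from several strategies are merged with per-method provenance.

## Synthetic fixtures

The generators emulate the statistical structure the method exploits and
nothing else: planted-partition graphs (blocks with high within / low
between edge probability), block-dominant annotation terms with a purity
parameter and Poisson extra terms (so OQ sees varying term counts), and
pathogens whose interactors concentrate in one home block
(`within_fraction`). Defaults — 4 blocks × 8 nodes, p_in = 0.8,
p_out = 0.02, 4 pathogens with 6 interactors each at within_fraction 1.0 —
are sized so the full pipeline runs in seconds while the planted
enrichment signal is strong enough to clear the hypergeometric
significance filter. They deliberately do not model PPI degree
distributions, assay-specific noise, or annotation incompleteness, so
passing tests demonstrate algorithmic correctness and recoverability of
planted structure, not performance on real interactomes.

One structural caveat the fixtures expose: statistically identical planted
blocks are *topologically* identical, so the unrestricted (location-free)
edge-GDV-similarity cannot tell their edges apart — that is the measure
working as designed, not failing. Planted-block recovery therefore uses
the adjacent-only similarity scope, which confines merging to connected
edge groups; on real networks the unrestricted scope is the method's
distinguishing capability.

## Numerical and degenerate-input choices

- Self-loops and duplicate edge-list rows are dropped with logged
  warnings; node ids are opaque strings.
- Similarity matrices are dense (desk scale); the pairwise kernel streams
  row by row to bound peak memory.
- `f_score := 0` when precision + recall = 0; precision := 0 when nothing
  is predicted.
- Empty universes, out-of-range K, inconsistent hypergeometric counts and
  mismatched vector lengths raise `ValueError` with diagnostics.
- All randomness (k-medoids initialization, baseline redraws, fixture
  generation) flows through explicit integer seeds.
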