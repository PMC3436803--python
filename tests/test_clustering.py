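"""Single-linkage, dendrogram cutting, partition density, k-medoids, filters."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from egdv.cluster import (
    Partition,
    cut,
    degree_filter,
    k_medoids,
    kmedoids_cost,
    partition_density,
    select_partition,
    single_linkage,
)
from oracles import threshold_clusters


def sim_matrix(items, pairs, default=0.0):
    n = len(items)
    idx = {x: i for i, x in enumerate(items)}
    sim = np.full((n, n), default)
    np.fill_diagonal(sim, 1.0)
    for (a, b), s in pairs.items():
        sim[idx[a], idx[b]] = sim[idx[b], idx[a]] = s
    return sim


class TestSingleLinkage:
    def test_forced_merge_order(self):
        items = ["A", "B", "C"]
        sim = sim_matrix(items, {("A", "B"): 0.9, ("A", "C"): 0.1, ("B", "C"): 0.1})
        dend = single_linkage(items, sim)
        assert [m[2] for m in dend.merges] == [0.9, 0.1]
        assert cut(dend, 2).clusters() in ({0: ["A", "B"], 1: ["C"]},)

    def test_two_tight_pairs_recovered_at_k2(self):
        items = ["A", "B", "C", "D"]
        sim = sim_matrix(items, {("A", "B"): 0.9, ("C", "D"): 0.9}, default=0.05)
        part = cut(single_linkage(items, sim), 2)
        groups = {frozenset(v) for v in part.clusters().values()}
        assert groups == {frozenset("AB"), frozenset("CD")}

    def test_single_item_degenerate(self):
        dend = single_linkage(["A"], np.ones((1, 1)))
        assert dend.merges == []

    def test_merge_similarities_non_increasing(self):
        rng = np.random.default_rng(3)
        n = 12
        sim = rng.uniform(0, 1, (n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        dend = single_linkage(list(range(n)), sim)
        sims = [m[2] for m in dend.merges]
        assert sims == sorted(sims, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_scipy_single_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        sim = rng.uniform(0, 1, (n, n))
        sim = (sim + sim.T) / 2  # distinct values: ties almost surely absent
        np.fill_diagonal(sim, 1.0)
        items = list(range(n))
        dend = single_linkage(items, sim)
        z = linkage(squareform(1 - sim, checks=False), method="single")
        for K in range(1, n + 1):
            ours = cut(dend, K)
            labels_ours = [ours.assignment[i] for i in items]
            labels_scipy = fcluster(z, K, criterion="maxclust")
            assert adjusted_rand_score(labels_ours, labels_scipy) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_threshold_components(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 9
        sim = np.round(rng.uniform(0, 1, (n, n)), 1)  # coarse grid forces ties
        sim = np.maximum(sim, sim.T)
        np.fill_diagonal(sim, 1.0)
        items = [f"i{k}" for k in range(n)]
        dend = single_linkage(items, sim)
        levels = sorted({m[2] for m in dend.merges}, reverse=True)
        for thr in levels:
            n_apply = sum(1 for m in dend.merges if m[2] >= thr)
            part = cut(dend, n - n_apply)
            ours = {frozenset(v) for v in part.clusters().values()}
            assert ours == threshold_clusters(items, sim, thr)


class TestCut:
    def test_extreme_cuts(self):
        items = list("ABCD")
        sim = sim_matrix(items, {("A", "B"): 0.9, ("C", "D"): 0.8}, default=0.1)
        dend = single_linkage(items, sim)
        assert cut(dend, 1).K == 1
        assert cut(dend, 4).K == 4
        with pytest.raises(ValueError):
            cut(dend, 0)
        with pytest.raises(ValueError):
            cut(dend, 5)

    def test_tied_levels_cut_together(self):
        items = list("ABCD")
        sim = sim_matrix(items, {}, default=0.5)  # every merge at the same level
        dend = single_linkage(items, sim)
        assert cut(dend, 2).K == 1  # cutting inside the tie block completes it


class TestPartitionDensity:
    def test_triangle_single_cluster(self):
        part = Partition({("a", "b"): 0, ("b", "c"): 0, ("a", "c"): 0}, kind="edge")
        d, d_c = partition_density(part)
        assert d == pytest.approx(1.0, abs=1e-12)
        assert d_c[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_edge_cluster_defined_zero(self):
        part = Partition({("a", "b"): 0, ("c", "d"): 1}, kind="edge")
        _, d_c = partition_density(part)
        assert d_c[0] == 0.0 and d_c[1] == 0.0

    def test_clique_edge_set_saturates(self):
        edges = [(f"v{i}", f"v{j}") for i in range(5) for j in range(i + 1, 5)]
        part = Partition({e: 0 for e in edges}, kind="edge")
        d, d_c = partition_density(part)
        assert d_c[0] == pytest.approx(1.0)
        assert d == pytest.approx(1.0)

    def test_node_partition_rejected(self):
        with pytest.raises(ValueError):
            partition_density(Partition({"a": 0}, kind="node"))


class TestSelectPartition:
    def _triangle_dendrogram(self):
        items = [("a", "b"), ("a", "c"), ("b", "c")]
        sim = np.array([[1, 0.8, 0.6], [0.8, 1, 0.7], [0.6, 0.7, 1]])
        return single_linkage(items, sim)

    def test_max_density_picks_full_triangle(self):
        part = select_partition(self._triangle_dendrogram(), "max_density")
        assert part.K == 1
        assert partition_density(part)[0] == pytest.approx(1.0)

    def test_nonbinding_cc_cap_equals_max_density(self):
        dend = self._triangle_dendrogram()
        a = select_partition(dend, "max_density")
        b = select_partition(
            dend, "max_density_cc_capped", cc_cap=1.0, node_universe={"a", "b", "c"}
        )
        assert a.assignment == b.assignment

    def test_max_density_dominates_all_levels(self):
        rng = np.random.default_rng(8)
        items = [(f"u{i}", f"v{i}") for i in range(8)]
        sim = rng.uniform(0, 1, (8, 8))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        dend = single_linkage(items, sim)
        best = select_partition(dend, "max_density")
        best_d = partition_density(best)[0]
        for K in range(1, 9):
            d = partition_density(cut(dend, K, kind="edge"))[0]
            assert d <= best_d + 1e-12

    def test_best_overall_quality_prefers_planted_split(self):
        # two 3-edge triangles with pure annotations vs merging everything
        items = [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        within = {(i, j): 0.9 for i in range(3) for j in range(3) if i < j}
        within.update({(i, j): 0.9 for i in range(3, 6) for j in range(3, 6) if i < j})
        sim = np.full((6, 6), 0.1)
        for (i, j), s in within.items():
            sim[i, j] = sim[j, i] = s
        np.fill_diagonal(sim, 1.0)
        dend = single_linkage(items, sim)
        ann = {v: {"T1"} for v in "abc"} | {v: {"T2"} for v in "xyz"}
        part = select_partition(
            dend, "best_overall_quality", annotations=ann,
            node_universe=set("abcxyz"), kind="edge",
        )
        groups = {frozenset(ns) for ns in part.node_clusters().values()}
        assert groups == {frozenset("abc"), frozenset("xyz")}


class TestKMedoids:
    def _blocks(self, n=10):
        dist = np.full((n, n), 0.95)
        half = n // 2
        dist[:half, :half] = 0.1
        dist[half:, half:] = 0.1
        np.fill_diagonal(dist, 0.0)
        return [f"i{k}" for k in range(n)], dist

    def test_k_equals_n_zero_cost(self):
        items, dist = self._blocks()
        part, converged = k_medoids(items, len(items), dist, seed=0)
        assert converged and part.K == len(items)
        assert kmedoids_cost(part, items, dist) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_two_blocks_recovered_any_seed(self, seed):
        items, dist = self._blocks()
        part, _ = k_medoids(items, 2, dist, seed=seed)
        groups = {frozenset(v) for v in part.clusters().values()}
        assert groups == {frozenset(items[:5]), frozenset(items[5:])}

    def test_cost_non_increasing_over_iterations(self):
        rng = np.random.default_rng(11)
        n = 20
        dist = rng.uniform(0.05, 1, (n, n))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        items = list(range(n))
        costs = []
        for t in range(1, 8):
            part, _ = k_medoids(items, 4, dist, seed=5, max_iter=t)
            costs.append(kmedoids_cost(part, items, dist))
        assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_seeded_reproducibility(self):
        items, dist = self._blocks()
        a, _ = k_medoids(items, 3, dist, seed=42)
        b, _ = k_medoids(items, 3, dist, seed=42)
        assert a.assignment == b.assignment

    def test_invalid_k(self):
        items, dist = self._blocks()
        with pytest.raises(ValueError):
            k_medoids(items, 0, dist, seed=0)


class TestDegreeFilter:
    def test_zero_threshold_keeps_everything(self, triangle):
        nodes, edges = degree_filter(triangle, 0)
        assert nodes == {"a", "b", "c"} and len(edges) == 3

    def test_star_keeps_only_hub(self):
        import networkx as nx

        star = nx.star_graph(4)
        nodes, edges = degree_filter(star, 3)
        assert nodes == {0} and edges == set()

    def test_five_clique_untouched(self):
        import networkx as nx

        g = nx.complete_graph(5)
        nodes, edges = degree_filter(g, 3)
        assert len(nodes) == 5 and len(edges) == 10


class TestPartitionViews:
    def test_edge_partition_induces_overlapping_memberships(self):
        part = Partition({("a", "b"): 0, ("b", "c"): 1}, kind="edge")
        mem = part.node_memberships()
        assert mem["b"] == {0, 1}
        assert mem["a"] == {0} and mem["c"] == {1}

    def test_every_clustered_node_covered(self):
        part = Partition(
            {("a", "b"): 0, ("b", "c"): 0, ("c", "d"): 1}, kind="edge"
        )
        mem = part.node_memberships()
        assert set(mem) == {"a", "b", "c", "d"}
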