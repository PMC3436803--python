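"""Eligibility rules, hypergeometric tails, LOOCV sweeps and predictions."""

import networkx as nx
import numpy as np
import pytest

from egdv.enrichment import (
    PathogenMap,
    eligible_universe,
    enrichment_table,
    f_score,
    hypergeom_pvalue,
    loocv_pr_curve,
    predict_new,
    random_baseline,
)
from oracles import exhaustive_hypergeom_tail


def high_degree_graph(nodes):
    """Every listed node wired to 4 private spokes => degree > 3 for all."""
    g = nx.Graph()
    for v in nodes:
        for i in range(4):
            g.add_edge(v, f"{v}_spoke{i}")
    return g


class TestEligibleUniverse:
    def test_single_interactor_pathogen_dropped(self):
        g = high_degree_graph(["a", "b", "c", "d", "e"])
        pmap = PathogenMap.from_pairs(
            [("a", "P1"), ("b", "P1"), ("c", "P2"), ("d", "P2"), ("e", "P3")]
        )
        universe, filtered = eligible_universe(g, pmap, 3)
        assert set(filtered.pathogen_to_proteins) == {"P1", "P2"}
        assert universe == {"a", "b", "c", "d"}

    def test_low_degree_interactors_do_not_count(self):
        g = high_degree_graph(["a", "b"])
        g.add_edge("low", "a")  # degree 1
        pmap = PathogenMap.from_pairs([("a", "P1"), ("low", "P1"), ("b", "P2")])
        with pytest.raises(ValueError):
            # P1 has one eligible interactor, P2 one: nothing survives
            eligible_universe(g, pmap, 3)

    def test_fully_eligible_map_unchanged(self):
        g = high_degree_graph(["a", "b", "c"])
        pmap = PathogenMap.from_pairs(
            [("a", "P1"), ("b", "P1"), ("b", "P2"), ("c", "P2")]
        )
        universe, filtered = eligible_universe(g, pmap, 3)
        assert filtered.associations == pmap.associations
        assert universe == {"a", "b", "c"}


class TestHypergeometric:
    def test_zero_successes_certain(self):
        assert hypergeom_pvalue(10, 5, 4, 0) == 1.0

    def test_worked_example(self):
        assert hypergeom_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_monotone_in_p(self):
        vals = [hypergeom_pvalue(20, 8, 6, p) for p in range(7)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        P = int(rng.integers(1, N + 1))
        C = int(rng.integers(1, N + 1))
        p = int(rng.integers(0, min(P, C) + 1))
        assert hypergeom_pvalue(N, P, C, p) == pytest.approx(
            exhaustive_hypergeom_tail(N, P, C, p), abs=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 4, 5)


class TestFScore:
    def test_harmonic_mean_of_equals(self):
        assert f_score(0.3, 0.3) == pytest.approx(0.3)

    def test_printed_precision_recall_pair(self):
        assert f_score(0.18, 0.30) == pytest.approx(0.225)

    def test_zero_convention(self):
        assert f_score(0.0, 0.0) == 0.0


def small_study():
    """Two clean PI modules plus a diffuse background pathogen.

    24 high-degree proteins in clusters of 4; PX's interactors fill cluster
    0, PY's fill 3/4 of cluster 1, and background pathogen PZ interacts
    with everything else (so the eligible universe is large enough for the
    module enrichments to reach significance while PZ's own enrichments
    stay random-like).
    """
    members = [f"m{i:02d}" for i in range(24)]
    g = high_degree_graph(members)
    clusters = {c: set(members[4 * c : 4 * c + 4]) for c in range(6)}
    pairs = (
        [(m, "PX") for m in members[0:4]]
        + [(m, "PY") for m in members[4:7]]
        + [(m, "PZ") for m in members[8:24]]
    )
    pmap = PathogenMap.from_pairs(pairs)
    universe, pmap = eligible_universe(g, pmap, 3)
    return clusters, pmap, universe


class TestLOOCV:
    def test_tp_plus_fn_is_constant(self):
        clusters, pmap, universe = small_study()
        curve = loocv_pr_curve(clusters, pmap, universe)
        n_known = curve.n_known
        assert n_known == 23  # every association involves a clustered protein
        tp = curve.recall * n_known
        fn = n_known - tp
        np.testing.assert_allclose(tp + fn, n_known)

    def test_recall_non_increasing_in_k(self):
        clusters, pmap, universe = small_study()
        curve = loocv_pr_curve(clusters, pmap, universe)
        assert all(b <= a + 1e-12 for a, b in zip(curve.recall, curve.recall[1:]))

    def test_k_100_yields_no_predictions(self):
        clusters, pmap, universe = small_study()
        curve = loocv_pr_curve(clusters, pmap, universe)
        assert curve.f_score[100] == 0.0 and curve.n_predictions[100] == 0

    def test_pure_modules_recovered_at_k66(self):
        clusters, pmap, universe = small_study()
        curve = loocv_pr_curve(clusters, pmap, universe)
        # hiding a PX member leaves 3/4 = 75% > 66; a PY member 2/3 > 66;
        # PZ's diffuse enrichments never reach significance
        assert curve.recall[66] == pytest.approx(7 / 23)
        assert curve.precision[66] == pytest.approx(7 / 8)  # one FP: m07-PY
        assert curve.f_score[66] > 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            loocv_pr_curve({}, PathogenMap(frozenset()), set())


class TestRandomBaseline:
    def test_seeded_reproducibility(self):
        clusters, pmap, universe = small_study()
        a = random_baseline(clusters, pmap, universe, runs=2, seed=9)
        b = random_baseline(clusters, pmap, universe, runs=2, seed=9)
        np.testing.assert_array_equal(a.f_score, b.f_score)

    def test_no_associations_no_signal(self):
        clusters, _, universe = small_study()
        empty = PathogenMap(frozenset())
        curve = random_baseline(clusters, empty, universe, runs=2, seed=0)
        assert (curve.f_score == 0).all()

    def test_planted_module_beats_randomized_clusters(self):
        clusters, pmap, universe = small_study()
        data = loocv_pr_curve(clusters, pmap, universe)
        rand = random_baseline(clusters, pmap, universe, runs=20, seed=3)
        assert data.f_score[50] > rand.f_score[50]


class TestPredictNew:
    def test_fully_associated_cluster_adds_nothing(self):
        clusters, pmap, universe = small_study()
        preds = predict_new({0: clusters[0]}, pmap, universe, k=50)
        assert [p for p in preds if p.pathogen == "PX"] == []

    def test_two_of_three_cluster_yields_one_prediction(self):
        members = [f"m{i:02d}" for i in range(20)]
        g = high_degree_graph(members)
        pmap = PathogenMap.from_pairs(
            [(members[0], "PX"), (members[1], "PX")]
            + [(m, "PY") for m in members[2:]]
        )
        universe, pmap = eligible_universe(g, pmap, 3)
        clusters = {0: set(members[0:3])}
        # enrichment 2/3 > 66%, p-value 18/1140 < 0.05 => predict the third
        preds = predict_new(clusters, pmap, universe, k=66)
        assert [(p.protein, p.pathogen) for p in preds] == [(members[2], "PX")]
        assert preds[0].enrichment == pytest.approx(2 / 3)

    def test_k_100_empty(self):
        clusters, pmap, universe = small_study()
        assert predict_new(clusters, pmap, universe, k=100) == []


class TestEnrichmentTable:
    def test_record_consistency(self):
        clusters, pmap, universe = small_study()
        for rec in enrichment_table(clusters, pmap, universe):
            assert rec.p <= min(rec.P, rec.C) <= rec.N
            assert 0 < rec.enrichment <= 1
            assert 0 < rec.p_value <= 1
            assert rec.enrichment == pytest.approx(rec.p / rec.C)
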