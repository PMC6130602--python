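import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevo import go_eval

ROOT, P, A, B, C = ("GO:0000001", "GO:0000002", "GO:0000003",
                    "GO:0000004", "GO:0000005")


class TestParseObo:
    def test_terms_and_edges(self, toy_dag):
        assert sorted(toy_dag.terms) == [ROOT, P, A, B, C]
        assert toy_dag.graph.number_of_edges() == 4

    def test_obsolete_excluded(self, toy_dag):
        assert "GO:0000006" not in toy_dag

    def test_namespace_restriction(self, toy_dag, toy_obo_path):
        assert "GO:0000007" not in toy_dag
        every = go_eval.parse_obo(toy_obo_path, namespace=None)
        assert "GO:0000007" in every

    def test_ancestor_closure_matches_brute_force(self, toy_dag):
        import networkx as nx
        for term in toy_dag.terms:
            brute = nx.descendants(toy_dag.graph, term) | {term}
            assert toy_dag.ancestors(term) == brute


class TestTermSimilarity:
    def test_identity_is_one(self, toy_dag):
        for term in toy_dag.terms:
            assert go_eval.term_similarity(toy_dag, term, term) == 1.0

    def test_sibling_hand_oracle(self, toy_dag):
        # S_a = {a: 1, p: 0.8, root: 0.64}; shared {p, root}:
        # (0.8 + 0.8 + 0.64 + 0.64) / (2.44 + 2.44) = 2.88 / 4.88
        assert go_eval.term_similarity(toy_dag, A, B) == pytest.approx(
            2.88 / 4.88, abs=1e-9)

    def test_part_of_weight(self, toy_dag):
        s = toy_dag.s_values(C)
        assert s == pytest.approx({C: 1.0, P: 0.6, ROOT: 0.48})
        # shared ancestors of a and c: p and root
        expect = (0.8 + 0.6 + 0.64 + 0.48) / (2.44 + 2.08)
        assert go_eval.term_similarity(toy_dag, A, C) == pytest.approx(
            expect, abs=1e-9)

    def test_root_only_overlap_formula(self, toy_dag):
        # p vs a shares {p, root}: full ancestor-chain overlap differs from
        # the root-only case, computed here from the S-values directly
        sa, sp = toy_dag.s_values(A), toy_dag.s_values(P)
        shared = set(sa) & set(sp)
        expect = sum(sa[t] + sp[t] for t in shared) / (
            sum(sa.values()) + sum(sp.values()))
        assert go_eval.term_similarity(toy_dag, A, P) == pytest.approx(expect)

    def test_symmetry(self, toy_dag):
        for u, v in itertools.combinations(toy_dag.terms, 2):
            suv = go_eval.term_similarity(toy_dag, u, v)
            assert suv == go_eval.term_similarity(toy_dag, v, u)
            assert 0.0 <= suv <= 1.0

    def test_unknown_term(self, toy_dag):
        with pytest.raises(KeyError):
            go_eval.term_similarity(toy_dag, A, "GO:9999999")


class TestGeneSimilarity:
    def test_identical_singletons(self, toy_dag):
        annot = {"g1": {A}, "g2": {A}}
        assert go_eval.gene_similarity(toy_dag, annot, "g1", "g2") == 1.0

    def test_reduces_to_term_similarity(self, toy_dag):
        annot = {"g1": {A}, "g2": {B}}
        assert go_eval.gene_similarity(toy_dag, annot, "g1", "g2") == \
            go_eval.term_similarity(toy_dag, A, B)

    def test_two_versus_one_hand_oracle(self, toy_dag):
        annot = {"g1": {A, B}, "g2": {A}}
        sab = go_eval.term_similarity(toy_dag, A, B)
        expect = (1.0 + sab + 1.0) / 3.0
        assert go_eval.gene_similarity(toy_dag, annot, "g1", "g2") == \
            pytest.approx(expect)

    def test_unannotated_rejected(self, toy_dag):
        with pytest.raises(ValueError):
            go_eval.gene_similarity(toy_dag, {"g1": {A}}, "g1", "g2")

    def test_propagated_annotations_are_ancestor_closures(self, toy_dag):
        annot = {"g1": {A}, "g2": set()}
        prop = go_eval.propagate_annotations(toy_dag, annot)
        assert prop["g1"] == {A, P, ROOT}
        assert prop["g2"] == set()
        # propagation can only raise the similarity of related genes
        base = go_eval.gene_similarity(toy_dag, {"g1": {A}, "g3": {B}},
                                       "g1", "g3")
        full = go_eval.gene_similarity(
            toy_dag, go_eval.propagate_annotations(
                toy_dag, {"g1": {A}, "g3": {B}}), "g1", "g3")
        assert full >= base


class TestClusteringScore:
    def test_identical_pairs_score_one(self, toy_dag):
        annot = {f"g{i}": {A} for i in range(4)}
        clusters = {"g0": 1, "g1": 1, "g2": 2, "g3": 2}
        overall, per_cluster, excluded = go_eval.clustering_score(
            toy_dag, annot, clusters)
        assert overall == 1.0
        assert excluded == []

    def test_size_weighting(self, toy_dag):
        annot = {"g0": {A}, "g1": {A},
                 "g2": {A}, "g3": {A}, "g4": {B}, "g5": {C}}
        clusters = {"g0": 1, "g1": 1, "g2": 2, "g3": 2, "g4": 2, "g5": 2}
        overall, per_cluster, _ = go_eval.clustering_score(
            toy_dag, annot, clusters)
        s2, s4 = per_cluster[1], per_cluster[2]
        assert overall == pytest.approx((2 * s2 + 4 * s4) / 6)

    def test_singletons_excluded(self, toy_dag):
        annot = {"g0": {A}, "g1": {A}, "g2": {B}}
        overall, per_cluster, excluded = go_eval.clustering_score(
            toy_dag, annot, {"g0": 1, "g1": 1, "g2": 2})
        assert excluded == [2]
        assert overall == 1.0

    def test_random_relabelling_lowers_structured_score(self, toy_dag):
        # functionally structured toy data: clusters of identical annotation
        annot = {}
        clusters = {}
        for i in range(6):
            annot[f"a{i}"] = {A}
            clusters[f"a{i}"] = 1
            annot[f"b{i}"] = {C}
            clusters[f"b{i}"] = 2
        observed, _, _ = go_eval.clustering_score(toy_dag, annot, clusters)
        null = go_eval.relabel_null(toy_dag, annot, clusters, n_sets=100,
                                    seed=11)
        assert observed == 1.0
        assert null.mean() < observed
        assert (null <= observed).all()


class TestRelabelNull:
    def test_sizes_preserved_and_deterministic(self, toy_dag):
        annot = {f"g{i}": {A if i % 2 else B} for i in range(6)}
        clusters = {f"g{i}": 1 + (i > 2) for i in range(6)}
        a = go_eval.relabel_null(toy_dag, annot, clusters, n_sets=5, seed=3)
        b = go_eval.relabel_null(toy_dag, annot, clusters, n_sets=5, seed=3)
        assert np.array_equal(a, b)

    def test_degenerate_identical_annotations(self, toy_dag):
        annot = {f"g{i}": {A} for i in range(6)}
        clusters = {f"g{i}": 1 + (i % 3) for i in range(6)}
        null = go_eval.relabel_null(toy_dag, annot, clusters, n_sets=4, seed=0)
        assert null == pytest.approx(np.ones(4))


def exhaustive_chi2_p(sizes, freq, observed_stat):
    """Exact p-value by enumerating which genes carry the term."""
    n = sum(sizes)
    expected = np.array([freq * s / n for s in sizes])
    labels = np.repeat(np.arange(len(sizes)), sizes)
    hits = 0
    total = 0
    for positions in itertools.combinations(range(n), freq):
        counts = np.bincount(labels[list(positions)], minlength=len(sizes))
        stat = ((counts - expected) ** 2 / expected).sum()
        hits += stat >= observed_stat - 1e-12
        total += 1
    return hits / total


class TestEnrichment:
    @pytest.fixture
    def toy_instance(self):
        # 3 clusters of sizes 4/4/2; term T on all genes of cluster 1 + g4
        clusters = {f"g{i}": 1 for i in range(4)}
        clusters.update({f"g{i}": 2 for i in range(4, 8)})
        clusters.update({f"g{i}": 3 for i in range(8, 10)})
        annot = {f"g{i}": {ROOT} for i in range(10)}  # keeps every gene annotated
        for i in range(5):
            annot[f"g{i}"] = annot[f"g{i}"] | {A}
        return clusters, annot

    def test_proportional_counts_give_zero_stat(self):
        clusters = {f"g{i}": 1 + i % 2 for i in range(8)}
        annot = {f"g{i}": {A} for i in range(8)}
        res = go_eval.enrichment_test(clusters, annot, n_resamples=200,
                                      min_freq=5, seed=0)
        row = res.set_index("term").loc[A]
        assert row["chi2"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_min_freq_excludes_rare_terms(self, toy_instance):
        clusters, annot = toy_instance
        annot["g9"] = annot["g9"] | {B}
        res = go_eval.enrichment_test(clusters, annot, n_resamples=100,
                                      min_freq=5, seed=0)
        assert B not in set(res["term"])  # frequency 1 < 5
        assert A in set(res["term"])

    def test_hand_worked_chi2_and_exhaustive_p(self):
        # 3 clusters of sizes 4/4/2, a frequency-5 term maximally
        # concentrated: 4 carriers in cluster 1, 1 in cluster 2, none in 3;
        # expected counts are 2/2/1
        clusters = {f"g{i}": 1 for i in range(4)}
        clusters.update({f"g{i}": 2 for i in range(4, 8)})
        clusters.update({f"g{i}": 3 for i in range(8, 10)})
        annot = {f"g{i}": {ROOT} for i in range(10)}
        carriers = ["g0", "g1", "g2", "g3", "g4"]
        for g in carriers:
            annot[g] = annot[g] | {A}
        res = go_eval.enrichment_test(clusters, annot, n_resamples=20_000,
                                      min_freq=5, seed=5)
        row = res.set_index("term").loc[A]
        want = (4 - 2) ** 2 / 2 + (1 - 2) ** 2 / 2 + (0 - 1) ** 2 / 1
        assert row["chi2"] == pytest.approx(want)
        exact = exhaustive_chi2_p([4, 4, 2], 5, want)
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(row["p"] - exact) <= 3 * se + 1 / 20_000

    def test_resampling_deterministic(self, toy_instance):
        clusters, annot = toy_instance
        a = go_eval.enrichment_test(clusters, annot, 500, 5, seed=9)
        b = go_eval.enrichment_test(clusters, annot, 500, 5, seed=9)
        assert a.equals(b)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert go_eval.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computation(self):
        assert go_eval.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_all_equal(self):
        assert go_eval.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx(
            [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_decreases_and_order_invariant(self, ps):
        adj = go_eval.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        perm = np.argsort(ps)
        adj_perm = go_eval.bh_adjust(np.asarray(ps)[perm])
        assert adj_perm == pytest.approx(adj[perm])


class TestBinomialOverrepresentation:
    def test_exact_tail_value(self):
        # k=8 of n=10 at p0=0.2: sum_{i>=8} C(10,i) 0.2^i 0.8^(10-i)
        clusters = {f"g{i}": 1 for i in range(10)}
        clusters.update({f"h{i}": 2 for i in range(40)})
        flagged = {f"g{i}" for i in range(8)} | {"h0", "h1"}
        assert len(flagged) / 50 == pytest.approx(0.2)
        res = go_eval.binomial_overrepresentation(clusters, flagged)
        row = res.set_index("cluster").loc[1]
        exact = sum(math.comb(10, i) * 0.2 ** i * 0.8 ** (10 - i)
                    for i in range(8, 11))
        assert row["p"] == pytest.approx(exact, abs=1e-12)
        assert exact == pytest.approx(7.79e-5, rel=1e-3)

    def test_zero_flagged_gives_p_one(self):
        clusters = {"a": 1, "b": 1, "c": 2, "d": 2}
        res = go_eval.binomial_overrepresentation(clusters, {"c"})
        assert res.set_index("cluster").loc[1, "p"] == pytest.approx(1.0)

    def test_proportional_cluster_not_significant(self):
        clusters = {f"g{i}": 1 + i % 2 for i in range(40)}
        flagged = {f"g{i}" for i in range(0, 40, 5)}  # 20% in each cluster
        res = go_eval.binomial_overrepresentation(clusters, flagged)
        assert (res["p"] > 0.4).all()
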