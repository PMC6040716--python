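import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coregnet.semsim import (
    AnnotationMap,
    GODag,
    gene_similarity,
    ks_greater,
    motif_homogeneity,
    permutation_null,
    read_annotations,
    read_obo,
    term_similarity,
    validate_motif_homogeneity,
    write_annotations,
    write_obo,
)
from coregnet.synthetic import simulate_go


@pytest.fixture
def chain_dag() -> GODag:
    # R <- A <- B, is_a edges of weight 0.8
    return GODag(
        parents={"R": [], "A": [("R", 0.8)], "B": [("A", 0.8)]},
        namespace={t: "biological_process" for t in "RAB"},
    )


@pytest.fixture
def synthetic_go():
    return simulate_go(seed=2)


class TestTermSimilarity:
    def test_identity_is_one(self, chain_dag):
        assert term_similarity("A", "A", chain_dag) == 1.0

    def test_three_term_chain_hand_value(self, chain_dag):
        # S_A = {A:1, R:0.8}; S_B = {B:1, A:0.8, R:0.64}
        expected = (1 + 0.8 + 0.8 + 0.64) / (1.8 + 2.44)
        assert term_similarity("A", "B", chain_dag) == pytest.approx(expected)
        assert term_similarity("A", "B", chain_dag) == pytest.approx(0.764, abs=5e-4)

    def test_distant_leaves_share_root_floor(self, synthetic_go):
        dag, _, _ = synthetic_go
        leaves = [t for t in sorted(dag.terms) if not any(
            t == p for ps in dag.parents.values() for p, _ in ps
        )]
        s = term_similarity(leaves[0], leaves[-1], dag)
        assert 0 < s < 0.3

    def test_cross_namespace_rejected(self):
        dag = GODag(
            parents={"R1": [], "R2": [], "A": [("R1", 0.8)], "B": [("R2", 0.8)]},
            namespace={"R1": "biological_process", "A": "biological_process",
                       "R2": "molecular_function", "B": "molecular_function"},
        )
        with pytest.raises(ValueError, match="cross-namespace"):
            term_similarity("A", "B", dag)

    def test_unknown_term_rejected(self, chain_dag):
        with pytest.raises(KeyError):
            term_similarity("A", "nope", chain_dag)

    def test_symmetric_and_bounded(self, synthetic_go):
        dag, _, _ = synthetic_go
        terms = sorted(dag.terms)
        rng = np.random.default_rng(0)
        for _ in range(30):
            t1, t2 = (terms[i] for i in rng.integers(0, len(terms), 2))
            s12 = term_similarity(t1, t2, dag)
            s21 = term_similarity(t2, t1, dag)
            assert s12 == pytest.approx(s21, abs=1e-12)
            assert 0 <= s12 <= 1
            if t1 != t2:
                assert s12 < 1


class TestGeneSimilarity:
    def test_identical_annotation_sets_score_one(self, chain_dag):
        ann = AnnotationMap({"g1": {"A", "B"}, "g2": {"A", "B"}})
        assert gene_similarity("g1", "g2", ann, chain_dag) == pytest.approx(1.0)

    def test_singleton_sets_reduce_to_term_similarity(self, chain_dag):
        ann = AnnotationMap({"g1": {"A"}, "g2": {"B"}})
        assert gene_similarity("g1", "g2", ann, chain_dag) == pytest.approx(
            term_similarity("A", "B", chain_dag)
        )

    def test_symmetric(self, synthetic_go):
        dag, ann, _ = synthetic_go
        genes = ann.annotated(dag)[:8]
        for g1, g2 in itertools.combinations(genes, 2):
            assert gene_similarity(g1, g2, ann, dag) == pytest.approx(
                gene_similarity(g2, g1, ann, dag), abs=1e-12
            )

    def test_unannotated_gene_rejected(self, chain_dag):
        ann = AnnotationMap({"g1": {"A"}, "g2": set()})
        with pytest.raises(ValueError, match="annotation"):
            gene_similarity("g1", "g2", ann, chain_dag)


class TestMotifHomogeneity:
    def test_pair_count(self, synthetic_go):
        dag, ann, _ = synthetic_go
        genes = ann.annotated(dag)[:3]
        scores = motif_homogeneity(genes, ann, dag)
        assert len(scores) == 3  # C(3,2)

    def test_identically_annotated_clones_score_one(self, chain_dag):
        ann = AnnotationMap({f"g{i}": {"A", "B"} for i in range(4)})
        scores = motif_homogeneity([f"g{i}" for i in range(4)], ann, chain_dag)
        assert scores == pytest.approx([1.0] * 6)

    def test_too_few_annotated_genes_names_the_motif(self, chain_dag):
        ann = AnnotationMap({"g1": {"A"}, "g2": set()})
        with pytest.raises(ValueError, match="motif-7"):
            motif_homogeneity(["g1", "g2"], ann, chain_dag, motif_id="motif-7")

    def test_planted_cluster_scores_exceed_scattered(self, synthetic_go):
        dag, ann, truth = synthetic_go
        cluster = sorted(next(iter(truth.go_clusters.values())))
        rng = np.random.default_rng(1)
        background = [g for g in ann.annotated(dag) if g.startswith("BGG")]
        scattered = [background[i] for i in rng.choice(len(background), 8, False)]
        within = np.mean(motif_homogeneity(cluster, ann, dag))
        across = np.mean(motif_homogeneity(scattered, ann, dag))
        assert within > across


class TestPermutationNull:
    def test_pool_size_identity_and_determinism(self, synthetic_go):
        dag, ann, _ = synthetic_go
        one = permutation_null(2, ann, dag, n_perm=1, seed=0)
        assert len(one) == 1
        a = permutation_null(4, ann, dag, n_perm=10, seed=3)
        b = permutation_null(4, ann, dag, n_perm=10, seed=3)
        assert len(a) == 10 * 6  # n_perm * C(4,2)
        assert a == b

    def test_m_larger_than_universe_rejected(self, chain_dag):
        ann = AnnotationMap({"g1": {"A"}, "g2": {"B"}})
        with pytest.raises(ValueError, match="universe"):
            permutation_null(3, ann, chain_dag)


class TestKsGreater:
    def test_identical_samples_give_zero(self):
        x = [0.1, 0.5, 0.9]
        d, p = ks_greater(x, x)
        assert d == 0.0 and p == 1.0

    def test_complete_separation_gives_one(self):
        d, p = ks_greater([1.0] * 5, [0.0] * 5)
        assert d == 1.0
        assert p < 0.01

    def test_wrong_direction_gives_zero_statistic(self):
        d, _ = ks_greater([0.0] * 5, [1.0] * 5)
        assert d == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        obs=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        nul=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
    )
    def test_matches_brute_force_ecdf_sup(self, obs, nul):
        d, _ = ks_greater(obs, nul)
        support = sorted(set(obs) | set(nul))
        brute = max(
            np.mean([v <= x for v in nul]) - np.mean([v <= x for v in obs])
            for x in support
        )
        assert d == pytest.approx(max(brute, 0.0), abs=1e-12)

    def test_statistic_agrees_with_scipy(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(9)
        obs = rng.beta(3, 1, 150)  # stochastically large
        nul = rng.random(200)
        d, p = ks_greater(obs, nul)
        ref = ks_2samp(nul, obs, alternative="greater")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.2, abs=1e-4)


class TestValidation:
    def test_per_motif_and_pooled_results(self, synthetic_go):
        dag, ann, truth = synthetic_go
        clusters = {f"cl{i}": genes for i, genes in
                    enumerate(truth.go_clusters.values())}
        results = validate_motif_homogeneity(clusters, ann, dag, n_perm=30, seed=4)
        ids = [r.motif_id for r in results]
        assert set(ids) == set(clusters) | {"pooled"}
        for r in results:
            assert 0 <= r.D <= 1 and 0 <= r.p <= 1
            if r.motif_id != "pooled":
                assert r.p < 0.01  # planted clusters are homogeneous
        cdf = results[-1].cdf_table()
        assert ((cdf[["F_obs", "F_null"]].diff().fillna(0)) >= -1e-12).all().all()


class TestIO:
    def test_obo_and_annotation_round_trip(self, tmp_path, synthetic_go):
        dag, ann, _ = synthetic_go
        obo = tmp_path / "toy.obo"
        gaf = tmp_path / "ann.tsv"
        write_obo(dag, obo)
        write_annotations(ann, gaf)
        dag2 = read_obo(obo)
        ann2 = read_annotations(gaf)
        assert dag2.terms == dag.terms
        assert dag2.namespace == dag.namespace
        assert {t: sorted(ps) for t, ps in dag2.parents.items()} == {
            t: sorted(ps) for t, ps in dag.parents.items()
        }
        assert ann2.gene_terms == ann.gene_terms
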