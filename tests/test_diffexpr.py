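import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coregnet.diffexpr import (
    _permutation_d,
    auc_roc,
    consensus_de,
    exclusive_de,
    moderated_t,
    run_comparison,
    sam_permutation_fdr,
    sam_statistic,
)
from coregnet.expression import ExpressionMatrix, GroupDesign


def _matrix(rows, samples=None) -> ExpressionMatrix:
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples),
        scale="log2",
    )


GROUP_A = ["s0", "s1", "s2"]
GROUP_B = ["s3", "s4", "s5"]


class TestSamStatistic:
    def test_zero_pooled_se_with_fudge(self):
        m = _matrix([[0, 0, 0, 1, 1, 1]])
        res = sam_statistic(m, GROUP_A, GROUP_B, s0=0.5)
        assert res.d.iloc[0] == pytest.approx(2.0)

    def test_identical_groups_give_zero(self):
        m = _matrix([[2, 3, 4, 2, 3, 4]])
        res = sam_statistic(m, GROUP_A, GROUP_B, s0=0.1)
        assert res.d.iloc[0] == pytest.approx(0.0)

    def test_s0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(0, 1, (20, 6)))
        res = sam_statistic(m, GROUP_A, GROUP_B, s0=0.0)
        a = m.values[GROUP_A].to_numpy()
        b = m.values[GROUP_B].to_numpy()
        t_ref = stats.ttest_ind(b, a, axis=1).statistic
        assert np.allclose(res.d, t_ref, atol=1e-9)

    def test_sign_matches_mean_difference_and_shrinks_with_s0(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(0, 1, (30, 6)) + np.r_[np.zeros(3), np.ones(3)])
        small = sam_statistic(m, GROUP_A, GROUP_B, s0=0.1).d
        large = sam_statistic(m, GROUP_A, GROUP_B, s0=1.0).d
        diff = (
            m.values[GROUP_B].mean(axis=1) - m.values[GROUP_A].mean(axis=1)
        )
        nonzero = np.abs(diff) > 1e-12
        assert (np.sign(small[nonzero]) == np.sign(diff[nonzero])).all()
        assert (np.abs(large[nonzero]) < np.abs(small[nonzero])).all()


class TestSamPermutationFdr:
    def test_infinite_delta_calls_nothing(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(0, 1, (40, 6)))
        res = sam_statistic(m, GROUP_A, GROUP_B)
        out = sam_permutation_fdr(res, m, GROUP_A, GROUP_B, delta=np.inf, seed=0)
        assert not out.called.any()

    def test_pure_noise_has_high_fdr(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(0, 1, (100, 6)))
        res = sam_statistic(m, GROUP_A, GROUP_B)
        out = sam_permutation_fdr(res, m, GROUP_A, GROUP_B, delta=0.05, seed=0)
        assert out.called.sum() > 0
        assert out.fdr > 0.5  # essentially every call is false

    def test_three_v_three_enumerates_all_labelings(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (10, 6))
        perm = _permutation_d(X, 3, n_perm=1000, s0=0.1, rng=rng)
        assert perm.shape[0] == 20  # C(6,3)

    def test_auto_delta_separates_strong_signal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.3, (60, 12))
        X[:10, 6:] += 3.0
        m = _matrix(X)
        a = [f"s{i}" for i in range(6)]
        b = [f"s{i}" for i in range(6, 12)]
        res = sam_statistic(m, a, b)
        out = sam_permutation_fdr(res, m, a, b, target_fdr=0.05, n_perm=100, seed=0)
        called = set(out.called.index[out.called])
        assert {f"g{i}" for i in range(10)} <= called
        assert len(called) <= 14
        # q monotone in |d|
        order = np.argsort(-np.abs(out.d.to_numpy()))
        assert (np.diff(out.q.to_numpy()[order]) >= -1e-12).all()


class TestModeratedT:
    def test_prior_df_zero_is_plain_t(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(0, 1, (25, 6)))
        res = moderated_t(m, GROUP_A, GROUP_B, prior_df=0.0)
        a = m.values[GROUP_A].to_numpy()
        b = m.values[GROUP_B].to_numpy()
        t_ref = stats.ttest_ind(b, a, axis=1)
        assert np.allclose(res.t, t_ref.statistic, atol=1e-9)
        assert np.allclose(res.p, t_ref.pvalue, atol=1e-9)

    def test_identical_gene_variances_reduce_to_plain_t(self):
        # every gene shows the same within-group spread, so shrinkage has no
        # target to move toward and the statistic equals the pooled t
        base = np.array([[-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]])
        m = _matrix(np.repeat(base, 15, axis=0) + np.arange(15)[:, None])
        res = moderated_t(m, GROUP_A, GROUP_B)
        t_ref = stats.ttest_ind(
            m.values[GROUP_B].to_numpy(), m.values[GROUP_A].to_numpy(), axis=1
        ).statistic
        assert np.allclose(res.t, t_ref, atol=1e-9)

    def test_variance_prior_parameter_recovery(self):
        # genes' true variances follow a scaled inverse-chi-square prior with
        # d0 = 4 and s0^2 = 0.25; moment matching should recover both
        rng = np.random.default_rng(7)
        n_genes, d0, s20 = 500, 4.0, 0.25
        sigma2 = s20 * d0 / rng.chisquare(d0, size=n_genes)
        X = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n_genes, 10))
        m = _matrix(X)
        a = [f"s{i}" for i in range(5)]
        b = [f"s{i}" for i in range(5, 10)]
        res = moderated_t(m, a, b)
        assert 0.5 * d0 <= res.df_prior <= 1.5 * d0
        assert 0.8 * s20 <= res.s2_prior <= 1.2 * s20

    def test_calls_invariant_to_gene_ordering(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (40, 6))
        X[:5, 3:] += 2.5
        m = _matrix(X)
        res = moderated_t(m, GROUP_A, GROUP_B)
        perm = rng.permutation(40)
        shuffled = ExpressionMatrix(m.values.iloc[perm], scale="log2")
        res_shuffled = moderated_t(shuffled, GROUP_A, GROUP_B)
        assert res.called_genes == res_shuffled.called_genes

    def test_single_gene_cannot_fit_prior(self):
        m = _matrix([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(ValueError, match="plain t-test"):
            moderated_t(m, GROUP_A, GROUP_B)


class TestAucRoc:
    @pytest.mark.parametrize(
        "a_vals, b_vals, expected",
        [
            ([1, 2, 3], [4, 5, 6], 1.0),
            ([1, 3], [2, 4], 0.75),
            ([1], [1], 0.5),
        ],
    )
    def test_hand_examples(self, a_vals, b_vals, expected):
        row = list(a_vals) + list(b_vals)
        m = _matrix([row])
        a = [f"s{i}" for i in range(len(a_vals))]
        b = [f"s{i}" for i in range(len(a_vals), len(row))]
        res = auc_roc(m, a, b)
        assert res.auc.iloc[0] == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a_vals=st.lists(st.integers(0, 6), min_size=1, max_size=8),
        b_vals=st.lists(st.integers(0, 6), min_size=1, max_size=8),
    )
    def test_matches_brute_force_pair_counting(self, a_vals, b_vals):
        row = [float(x) for x in a_vals + b_vals]
        m = _matrix([row])
        a = [f"s{i}" for i in range(len(a_vals))]
        b = [f"s{i}" for i in range(len(a_vals), len(row))]
        auc = auc_roc(m, a, b).auc.iloc[0]
        pairs = [
            1.0 if y > x else 0.5 if y == x else 0.0 for x in a_vals for y in b_vals
        ]
        assert auc == pytest.approx(float(np.mean(pairs)), abs=1e-12)
        # antisymmetry under group exchange
        auc_rev = auc_roc(m, b, a).auc.iloc[0]
        assert auc + auc_rev == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_rejected(self):
        m = _matrix([[1, 2, 3]])
        with pytest.raises(ValueError, match="non-empty"):
            auc_roc(m, [], ["s0", "s1", "s2"])


class TestConsensus:
    @pytest.mark.parametrize(
        "sets, min_methods, expected",
        [
            ([{"g1", "g2"}, {"g2", "g3"}, {"g2"}], 2, {"g2"}),
            ([{"g1", "g2"}, {"g1"}, {"g2"}], 2, {"g1", "g2"}),
            ([{"g1"}, {"g2"}, {"g3"}], 1, {"g1", "g2", "g3"}),
        ],
    )
    def test_vote_counting(self, sets, min_methods, expected):
        assert consensus_de(sets, min_methods=min_methods) == expected

    def test_requires_three_sets_and_valid_threshold(self):
        with pytest.raises(ValueError, match="3 method"):
            consensus_de([{"a"}, {"b"}])
        with pytest.raises(ValueError, match="1..3"):
            consensus_de([{"a"}, {"b"}, {"c"}], min_methods=4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        sets=st.lists(
            st.sets(st.sampled_from(list("abcdefgh"))), min_size=3, max_size=3
        )
    )
    def test_consensus_subset_of_union_and_order_free(self, sets):
        out = consensus_de(sets)
        assert out <= set().union(*sets)
        assert out == consensus_de(sets[::-1])


class TestExclusive:
    def test_set_difference_semantics(self):
        comps = {"c1": {"a", "b", "c"}, "c2": {"b"}, "c3": set()}
        assert exclusive_de(comps, "c1") == {"a", "c"}
        comps = {"c1": {"a"}, "c2": {"a", "b"}}
        assert exclusive_de(comps, "c1") == set()

    def test_explicit_exclusion_list(self):
        comps = {"c1": {"a", "b"}, "c2": {"a"}, "c3": {"b"}}
        assert exclusive_de(comps, "c1", exclude=["c2"]) == {"b"}

    def test_missing_focal_rejected(self):
        with pytest.raises(KeyError, match="focal"):
            exclusive_de({"c1": set(), "c2": set()}, "cX")

    def test_noiseless_planted_truth_table(self, small_design):
        """With noiseless consensus sets built from the planted expression
        patterns, subtracting the internal-reference comparisons recovers
        exactly the genes exclusive to the diabetic-EPC contrast."""
        planted_exclusive = {"e1", "e2"}  # shifted in D-EPC only: DE in 3,4,5
        diabetes_general = {"d1"}  # shifted in both diabetic groups: 1,4,5,6
        control_epc = {"n1"}  # shifted in ND-EPC only: 2,4,6
        comps = {
            "comp1": set(diabetes_general),
            "comp2": set(control_epc),
            "comp3": set(planted_exclusive),
            "comp4": planted_exclusive | diabetes_general | control_epc,
            "comp5": planted_exclusive | diabetes_general,
            "comp6": diabetes_general | control_epc,
        }
        exclude = small_design.reference_comparisons()
        assert exclusive_de(comps, "comp4", exclude=exclude) == planted_exclusive


class TestRunComparison:
    def test_consensus_respects_two_of_three(self):
        rng = np.random.default_rng(9)
        X = rng.normal(8, 0.5, (80, 24))
        X[:8, 18:] += 2.0  # strong shift in the case group of comp4
        samples = [f"{g}_{i}" for g in ("ND-Lin+", "D-Lin+", "ND-EPC", "D-EPC")
                   for i in range(6)]
        m = ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(80)], columns=samples),
            scale="log2",
        )
        design = GroupDesign(
            sample_to_group={s: s.rsplit("_", 1)[0] for s in samples}
        )
        cs = run_comparison(m, design, "comp4", seed=0)
        assert {f"g{i}" for i in range(8)} <= cs.consensus
        for g in cs.consensus:
            votes = sum(g in s for s in cs.method_calls.values())
            assert votes >= 2
        assert (cs.lfc.loc[[f"g{i}" for i in range(8)]] > 1.5).all()
        assert (cs.direction.loc[[f"g{i}" for i in range(8)]] == "up").all()
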