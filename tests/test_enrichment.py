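import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coregnet.enrichment import (
    bh_adjust,
    geneset_overlap_test,
    hypergeom_tail,
    mirna_enrichment,
    ora,
    read_gmt,
    write_gmt,
)


def exhaustive_urn_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) by enumerating every size-n draw from the urn."""
    hit = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hit += 1
    return Fraction(hit, total)


def tail_sum(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) as a sum of binomial-coefficient terms."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(n, K) + 1))
    return Fraction(num, math.comb(N, n))


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k, K, n, N, expected",
        [
            (0, 3, 2, 10, 1.0),
            (2, 2, 2, 4, 1 / 6),
            (4, 5, 4, 10, 5 / 210),
        ],
    )
    def test_hand_examples(self, k, K, n, N, expected):
        assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeom_tail(3, 2, 2, 4)  # k > min(n, K)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 5, 2, 4)  # K > N

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        N = data.draw(st.integers(1, 12))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        expected = float(exhaustive_urn_tail(k, K, n, N))
        assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_upper_plus_lower_tail_is_one(self, data):
        N = data.draw(st.integers(1, 200))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        from scipy.stats import hypergeom

        lower = float(hypergeom.cdf(k - 1, N, K, n))
        assert hypergeom_tail(k, K, n, N) + lower == pytest.approx(1.0, abs=1e-12)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_never_decreases_and_permutation_invariant(self, ps):
        q = np.asarray(bh_adjust(ps))
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        q_perm = np.asarray(bh_adjust([ps[i] for i in perm]))
        assert np.allclose(q_perm, q[perm], atol=1e-12)


class TestMirnaEnrichment:
    def test_perfect_overlap_is_top_hit(self):
        universe = {f"g{i}" for i in range(200)}
        de = {f"g{i}" for i in range(10)}
        assoc = {"mir-hit": set(de), "mir-miss": {f"g{i}" for i in range(100, 108)}}
        table = mirna_enrichment(de, assoc, universe)
        top = table.iloc[0]
        assert top["term"] == "mir-hit"
        assert top["significant"]
        miss = table.set_index("term").loc["mir-miss"]
        assert miss["k"] == 0
        assert miss["p"] == pytest.approx(1.0)
        assert not miss["significant"]

    def test_planted_mirnas_recovered_exactly(self):
        """5 planted miRNAs with heavy DE overlap among 50 tested: exactly the
        planted ones reach q <= 0.01, confirmed by a brute-force tail sum."""
        rng = np.random.default_rng(12)
        universe = {f"g{i}" for i in range(500)}
        de = {f"g{i}" for i in range(40)}
        background = sorted(universe - de)
        assoc = {}
        for i in range(5):
            hits = rng.choice(40, size=10, replace=False)
            noise = rng.choice(len(background), size=5, replace=False)
            assoc[f"mir-planted-{i}"] = (
                {f"g{j}" for j in hits} | {background[j] for j in noise}
            )
        for i in range(45):
            noise = rng.choice(len(background), size=15, replace=False)
            assoc[f"mir-bg-{i}"] = {background[j] for j in noise}
        table = mirna_enrichment(de, assoc, universe, alpha=0.01)
        called = set(table.loc[table["significant"], "term"])
        assert called == {f"mir-planted-{i}" for i in range(5)}
        # cross-check every raw p against the exact binomial-coefficient sum
        for row in table.itertuples():
            expected = float(tail_sum(row.k, row.K, row.n, row.N))
            assert row.p == pytest.approx(expected, rel=1e-9)

    def test_universe_pre_intersection_contract(self):
        universe = {f"g{i}" for i in range(50)}
        de = {f"g{i}" for i in range(8)}
        assoc = {"mir-1": {f"g{i}" for i in range(4)}}
        polluted = {"mir-1": assoc["mir-1"] | {"alien-1", "alien-2"}}
        a = mirna_enrichment(de, assoc, universe)
        b = mirna_enrichment(de, polluted, universe)
        assert a.drop(columns="members").equals(b.drop(columns="members"))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            mirna_enrichment(set(), {"m": set()}, {"g"})
        with pytest.raises(ValueError):
            mirna_enrichment({"g"}, {"m": set()}, set())


class TestOverlapTest:
    def test_disjoint_sets_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        t = geneset_overlap_test({"g0", "g1"}, {"g5", "g6"}, universe)
        assert t.k == 0 and t.p == pytest.approx(1.0)

    def test_degenerate_full_overlap_p_one(self):
        universe = {f"g{i}" for i in range(6)}
        t = geneset_overlap_test(universe, universe, universe)
        assert t.k == t.n == t.K == t.N and t.p == pytest.approx(1.0)

    def test_disease_scale_matches_tail_sum(self):
        # disease-list-scale test: 80-gene query, 266-gene annotation set
        N, K, n, k = 12000, 266, 80, 3
        universe = {f"g{i}" for i in range(N)}
        set_b = {f"g{i}" for i in range(K)}
        set_a = {f"g{i}" for i in range(K - k, K - k + n)}
        t = geneset_overlap_test(set_a, set_b, universe)
        assert t.k == k
        assert t.p == pytest.approx(float(tail_sum(k, K, n, N)), abs=1e-12)


class TestOra:
    def test_minimum_overlap_rule_excludes_terms(self):
        universe = {f"g{i}" for i in range(100)}
        query = {"g0", "g1", "g2"}
        sets = {"t-single": {"g0"}, "t-pair": {"g0", "g1"}}
        table = ora(query, sets, universe)
        assert set(table["term"]) == {"t-pair"}

    def test_identical_term_is_minimal_p(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(5)}
        sets = {"t-exact": set(query), "t-half": {"g0", "g1", "g50", "g51"}}
        table = ora(query, sets, universe).set_index("term")
        assert table.loc["t-exact", "p"] < table.loc["t-half", "p"]
        assert bool(table.loc["t-exact", "significant"])

    def test_alpha_one_reports_every_qualifying_term(self):
        rng = np.random.default_rng(4)
        universe = {f"g{i}" for i in range(60)}
        pool = sorted(universe)
        query = {pool[i] for i in rng.choice(60, size=12, replace=False)}
        sets = {
            f"t{j}": {pool[i] for i in rng.choice(60, size=10, replace=False)}
            for j in range(20)
        }
        table = ora(query, sets, universe, alpha=1.0)
        qualifying = [t for t, s in sets.items() if len(s & query) >= 2]
        assert sorted(table["term"]) == sorted(qualifying)
        assert table["significant"].all()


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = {"setA": {"g1", "g2"}, "setB": {"g3"}}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_one_field\n")
        with pytest.raises(ValueError, match="3 tab-separated"):
            read_gmt(path)
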