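"""Statistical kernel: exhaustive oracles, closed-form checks, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from regnet import stats_core as sc


def subset_enumeration_tail(k: int, K: int, n: int, N: int) -> float:
    """P(|S ∩ F| >= k) by enumerating every K-subset S against a fixed n-set."""
    total = hits = 0
    for subset in itertools.combinations(range(N), K):
        total += 1
        overlap = sum(1 for x in subset if x < n)
        if overlap >= k:
            hits += 1
    return hits / total


class TestHypergeomUpperTail:
    def test_zero_overlap_is_certain(self):
        assert sc.hypergeom_upper_tail(sc.OverlapQuery(0, 5, 8, 20)) == 1.0

    def test_forced_overlap_is_certain(self):
        # the n-set is contained in the K-set when both fill the universe side
        assert sc.hypergeom_upper_tail(sc.OverlapQuery(3, 10, 3, 10)) == 1.0

    def test_matches_subset_enumeration_spot_check(self):
        expected = subset_enumeration_tail(4, 5, 8, 20)
        got = sc.hypergeom_upper_tail(sc.OverlapQuery(4, 5, 8, 20))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_subset_enumeration_small_universes(self):
        cases = 0
        for N in range(1, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, K + n - N)
                    for k in range(lo, min(K, n) + 1):
                        expected = subset_enumeration_tail(k, K, n, N)
                        got = sc.hypergeom_upper_tail(sc.OverlapQuery(k, K, n, N))
                        assert got == pytest.approx(expected, abs=1e-12)
                        cases += 1
        assert cases > 500

    def test_rejects_impossible_margins(self):
        with pytest.raises(ValueError):
            sc.OverlapQuery(6, 5, 8, 20)
        with pytest.raises(ValueError):
            sc.OverlapQuery(0, 25, 8, 20)
        with pytest.raises(ValueError):
            sc.OverlapQuery(0, 8, 5, 10)  # below forced minimum of 3


class TestFisherOneSided:
    def test_minimum_a_cell_gives_one(self):
        assert sc.fisher_one_sided(sc.Table2x2(0, 4, 4, 0)) == 1.0

    def test_hand_summed_point_masses(self):
        # margins 4/4/4/4: P(a>=3) = [C(4,3)C(4,1) + C(4,4)C(4,0)] / C(8,4)
        assert sc.fisher_one_sided(sc.Table2x2(3, 1, 1, 3)) == pytest.approx(17 / 70)

    def test_single_extreme_table(self):
        assert sc.fisher_one_sided(sc.Table2x2(4, 0, 0, 4)) == pytest.approx(1 / 70)

    def test_equals_hypergeometric_upper_tail_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            t = sc.Table2x2(int(a), int(b), int(c), int(d))
            via_hg = sc.hypergeom_upper_tail(
                sc.OverlapQuery(t.a, t.a + t.b, t.a + t.c, t.total)
            )
            ours = sc.fisher_one_sided(t)
            assert ours == pytest.approx(via_hg, rel=1e-12)
            _, scipy_p = ss.fisher_exact(t.as_array(), alternative="greater")
            assert ours == pytest.approx(scipy_p, rel=1e-9)


class TestOddsRatio:
    def test_symmetric_table(self):
        assert sc.odds_ratio(sc.Table2x2(10, 10, 10, 10)) == (1.0, False)

    def test_direct_arithmetic(self):
        assert sc.odds_ratio(sc.Table2x2(20, 5, 5, 20)) == (16.0, False)

    def test_haldane_correction(self):
        ratio, corrected = sc.odds_ratio(sc.Table2x2(3, 0, 2, 5), "haldane")
        assert corrected
        assert ratio == pytest.approx((3.5 * 5.5) / (0.5 * 2.5))

    def test_strict_policy_raises_on_undefined(self):
        with pytest.raises(ZeroDivisionError):
            sc.odds_ratio(sc.Table2x2(3, 0, 2, 5), "strict")


class TestBHAdjust:
    def test_equal_ps_are_fixed_points(self):
        out = sc.bh_adjust([0.2, 0.2, 0.2])
        assert out.adjusted == pytest.approx((0.2, 0.2, 0.2))

    def test_hand_applied_step_up(self):
        out = sc.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out.adjusted == pytest.approx((0.04, 0.04, 0.04, 0.04))

    def test_singleton_identity(self):
        assert sc.bh_adjust([0.5]).adjusted == (0.5,)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            sc.bh_adjust([])
        with pytest.raises(ValueError):
            sc.bh_adjust([0.5, 1.2])

    def test_matches_scipy_step_up(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        ours = np.array(sc.bh_adjust(p).adjusted)
        scipy_adj = ss.false_discovery_control(p, method="bh")
        np.testing.assert_allclose(ours, scipy_adj, rtol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_dominance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = sc.bh_adjust(pvals).adjusted
        shuffled = sc.bh_adjust([pvals[i] for i in perm]).adjusted
        for out_i, in_i in enumerate(perm):
            assert shuffled[out_i] == pytest.approx(base[in_i])
        assert all(adj >= raw for adj, raw in zip(base, pvals))
        assert all(adj <= 1.0 for adj in base)


class TestPearsonChi2:
    def test_perfect_independence(self):
        stat, p = sc.pearson_chi2_2x2(sc.Table2x2(10, 10, 10, 10))
        assert stat == 0.0
        assert p == 1.0

    def test_closed_form_value(self):
        t = sc.Table2x2(5, 5, 5, 85)
        stat, p = sc.pearson_chi2_2x2(t)
        n = 100
        expected = n * (5 * 85 - 5 * 5) ** 2 / (10 * 90 * 10 * 90)
        assert stat == pytest.approx(expected)
        scipy_stat, scipy_p, _, _ = ss.chi2_contingency(t.as_array(), correction=False)
        assert stat == pytest.approx(scipy_stat)
        assert p == pytest.approx(scipy_p)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20)    :
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            s1, _ = sc.pearson_chi2_2x2(sc.Table2x2(a, b, c, d))
            s2, _ = sc.pearson_chi2_2x2(sc.Table2x2(a, c, b, d))
            assert s1 == pytest.approx(s2)

    def test_yates_correction_matches_scipy(self):
        t = sc.Table2x2(12, 5, 7, 20)
        stat, p = sc.pearson_chi2_2x2(t, continuity=True)
        scipy_stat, scipy_p, _, _ = ss.chi2_contingency(t.as_array(), correction=True)
        assert stat == pytest.approx(scipy_stat)
        assert p == pytest.approx(scipy_p)

    def test_zero_margin_degenerate(self):
        with pytest.raises(sc.DegenerateTableError):
            sc.pearson_chi2_2x2(sc.Table2x2(0, 0, 5, 5))


class TestNormalTwoSidedP:
    def test_center_of_null(self):
        assert sc.normal_two_sided_p(3.0, 3.0, 1.0) == 1.0

    def test_classic_quantile(self):
        assert sc.normal_two_sided_p(1.959964, 0.0, 1.0) == pytest.approx(0.05, abs=1e-6)

    def test_one_sided_tail_at_1_65(self):
        assert sc.normal_upper_tail(1.65) == pytest.approx(0.0495, abs=5e-4)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-50, 50), st.floats(0.01, 100), st.floats(0.01, 100))
    def test_symmetry_about_mean(self, mu, delta, sigma):
        left = sc.normal_two_sided_p(mu - delta, mu, sigma)
        right = sc.normal_two_sided_p(mu + delta, mu, sigma)
        assert left == pytest.approx(right, rel=1e-9)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            sc.normal_two_sided_p(0.0, 0.0, 0.0)
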