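"""Statistical core, each routine checked against an independent oracle."""

import itertools
import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from amylatlas.stats import (
    TwoByTwo,
    benjamini_hochberg,
    bonferroni,
    chi_square_2x2,
    fisher_exact,
    mann_whitney_u,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k), math.comb(n, row1))

    lo, hi = max(0, row1 - (n - col1)), min(col1, row1)
    p_obs = prob(a)
    return sum((p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs), Fraction(0))


def mwu_enumeration_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full rank-arrangement enumeration."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    counts = Counter()
    for comb in itertools.combinations(range(n1 + n2), n1):
        counts[ranks[list(comb)].sum() - n1 * (n1 + 1) / 2] += 1
    total = math.comb(n1 + n2, n1)
    cdf = sum(cnt for u, cnt in counts.items() if u <= u_obs) / total
    sf = sum(cnt for u, cnt in counts.items() if u >= u_obs) / total
    return min(1.0, 2 * min(cdf, sf))


def bh_stepup_oracle(pvals):
    """BH adjusted p by the step-up formula m*p(i)/i with cumulative minimum."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top
        running = min(running, m * pvals[idx] / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisher:
    def test_exchangeable_groups(self):
        assert fisher_exact(TwoByTwo(5, 5, 5, 5))[0] == pytest.approx(1.0)

    def test_single_extreme_table(self):
        p, odds = fisher_exact(TwoByTwo(4, 0, 0, 6))
        assert p == pytest.approx(1 / 210, abs=1e-12)
        assert odds == math.inf

    def test_zero_margin_degenerate(self):
        assert fisher_exact(TwoByTwo(0, 0, 3, 4))[0] == 1.0

    def test_matches_rational_oracle_on_small_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0 or max(a + b, c + d, a + c, b + d) > 8:
                continue
            p, _ = fisher_exact(TwoByTwo(a, b, c, d))
            assert abs(p - float(fisher_two_sided_oracle(a, b, c, d))) < 1e-10

    def test_one_sided_alternatives_sum_properly(self):
        t = TwoByTwo(7, 2, 3, 8)
        pg, _ = fisher_exact(t, "greater")
        pl, _ = fisher_exact(t, "less")
        # tails overlap exactly in the observed table's probability
        row1, col1, n = 9, 10, 20
        p_obs = sps.hypergeom.pmf(7, n, col1, row1)
        assert pg + pl == pytest.approx(1 + p_obs, rel=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact(TwoByTwo(int(a), int(b), int(c), int(d)))
            p_sp = sps.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(p_sp, rel=1e-7, abs=1e-12)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


class TestMultipleTesting:
    def test_bh_worked_list(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_equals_itself(self):
        assert benjamini_hochberg([0.037])[0] == pytest.approx(0.037)
        assert bonferroni([0.037])[0] == pytest.approx(0.037)

    def test_bonferroni_caps_at_one(self):
        assert bonferroni([0.5] * 10) == pytest.approx([1.0] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.2, 1.2])
        with pytest.raises(ValueError):
            bonferroni([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_matches_stepup_oracle_and_dominates_raw_under_bonferroni(self, pvals):
        adj = benjamini_hochberg(pvals)
        assert adj == pytest.approx(bh_stepup_oracle(pvals), abs=1e-12)
        assert np.all(bonferroni(pvals) >= np.asarray(pvals) - 1e-15)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms(use_true_random=False))
    def test_bh_permutation_invariant(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = benjamini_hochberg(pvals)
        adj_perm = benjamini_hochberg([pvals[i] for i in perm])
        unpermuted = np.empty(len(pvals))
        for out_pos, src in enumerate(perm):
            unpermuted[src] = adj_perm[out_pos]
        assert unpermuted == pytest.approx(adj, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert res.effect_size_r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))
        assert res.method == "exact"

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.effect_size_r == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0, abs=0.01)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        fwd = mann_whitney_u(x, y)
        rev = mann_whitney_u(y, x)
        assert fwd.effect_size_r == pytest.approx(-rev.effect_size_r)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 7))
            y = rng.normal(size=rng.integers(3, 7))
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(mwu_enumeration_oracle(x, y), abs=1e-12)

    def test_ties_fall_back_to_normal_approx(self):
        res = mann_whitney_u([1, 1, 2, 3], [1, 2, 2, 4])
        assert res.method == "normal_approx"
        assert 0 < res.p_value <= 1

    def test_z_effect_size_bounded_and_same_sign(self):
        x, y = [5, 6, 7, 8], [1, 2, 3, 4]
        rb = mann_whitney_u(x, y, effect_size="rank_biserial")
        z = mann_whitney_u(x, y, effect_size="z")
        assert abs(z.effect_size_r) <= 1
        assert math.copysign(1, z.effect_size_r) == math.copysign(1, rb.effect_size_r)

    def test_null_calibration_of_exact_test(self):
        # tie-free null: both samples from one continuous distribution
        rng = np.random.default_rng(2026)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            res = mann_whitney_u(x, y)
            rejections += res.p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


# ---------------------------------------------------------------------------
# chi-square / phi
# ---------------------------------------------------------------------------


class TestChiSquare:
    def test_perfect_association(self):
        assert chi_square_2x2(TwoByTwo(10, 0, 0, 10)).phi == pytest.approx(1.0)

    def test_no_association(self):
        res = chi_square_2x2(TwoByTwo(5, 5, 5, 5))
        assert res.chi2 == 0.0 and res.phi == 0.0

    def test_closed_form_value(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 60*450^2/(30*30*25*35)
        res = chi_square_2x2(TwoByTwo(20, 10, 5, 25))
        assert res.chi2 == pytest.approx(60 * 450**2 / (30 * 30 * 25 * 35))
        assert res.phi == pytest.approx(math.sqrt(res.chi2 / 60))

    def test_zero_margin_degenerate(self):
        res = chi_square_2x2(TwoByTwo(0, 0, 5, 5))
        assert (res.chi2, res.phi, res.p_value) == (0.0, 0.0, 1.0)

    def test_agrees_with_scipy_contingency(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 30, size=4))
            res = chi_square_2x2(TwoByTwo(a, b, c, d))
            chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert res.chi2 == pytest.approx(chi2)
            assert res.p_value == pytest.approx(p)

    def test_negative_association_sign(self):
        assert chi_square_2x2(TwoByTwo(1, 9, 9, 1)).phi < 0
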