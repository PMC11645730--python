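"""Group statistics: summaries, pooled t, summaries-only path, Fisher test."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmjmotion import (
    DirectionCounts,
    compare_directions,
    compare_from_summaries,
    compare_groups,
    summarize,
)
from tmjmotion.errors import StatsError


def fisher_two_sided_enumeration(a, b, c, d):
    """Exhaustive hypergeometric two-sided Fisher p for [[a, b], [c, d]].

    Sums P(X = x) over the support of X ~ Hypergeom for every table with the
    same margins whose probability does not exceed that of the observed one
    (with a small relative tolerance for float ties).
    """
    m, n, k = a + b, c + d, a + c
    lo, hi = max(0, k - n), min(m, k)
    total = math.comb(m + n, k)
    probs = {x: math.comb(m, x) * math.comb(n, k - x) / total for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize([1.0, 2.0, 3.0])
        assert (s.n, s.mean, s.sd) == (3, 2.0, 1.0)
        assert s.sem == pytest.approx(0.5774, abs=1e-4)

    def test_constant_values_flag_undefined_normality(self):
        s = summarize([4.0, 4.0, 4.0, 4.0])
        assert s.sd == 0.0
        assert s.normality_p is None

    def test_moments_match_direct_formulas(self):
        rng = np.random.default_rng(42)
        x = rng.normal(25.64, 7.26, size=44)
        s = summarize(x)
        assert s.mean == pytest.approx(float(np.sum(x)) / 44, abs=1e-9)
        var = float(np.sum((x - np.mean(x)) ** 2)) / 43
        assert s.sd == pytest.approx(math.sqrt(var), abs=1e-9)
        assert s.sem == pytest.approx(math.sqrt(var / 44), abs=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(StatsError):
            summarize([1.0])


class TestCompareGroups:
    def test_identical_groups_give_zero_diff_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        est = compare_groups(g, g)
        assert est.diff == 0.0
        assert est.p == pytest.approx(1.0)
        assert est.ci_low < 0 < est.ci_high
        assert est.test == "pooled_t"

    def test_hand_computed_pooled_t(self):
        """a={1,2,3}, b={4,5,6}: diff 3, se 0.8165, df 4, CI [0.733, 5.267]."""
        est = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert est.diff == pytest.approx(3.0)
        assert est.se == pytest.approx(math.sqrt(1.0 * (1 / 3 + 1 / 3)), abs=1e-9)
        assert est.se == pytest.approx(0.8165, abs=1e-4)
        assert est.df == 4
        assert est.ci_low == pytest.approx(3 - 2.7765 * 0.8165, abs=2e-3)
        assert est.ci_high == pytest.approx(3 + 2.7765 * 0.8165, abs=2e-3)

    def test_summary_path_reproduces_raw_t_path_exactly(self):
        rng = np.random.default_rng(7)
        a = rng.normal(25.0, 7.0, 44)
        b = rng.normal(29.0, 5.0, 37)
        raw = compare_groups(a, b)
        assert raw.test == "pooled_t"
        sa, sb = summarize(a), summarize(b)
        smry = compare_from_summaries(sa.mean, sa.sem, sa.n, sb.mean, sb.sem, sb.n)
        for attr in ("diff", "se", "ci_low", "ci_high", "df", "p"):
            assert getattr(smry, attr) == pytest.approx(getattr(raw, attr), abs=1e-9)

    def test_non_normal_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.normal(0, 1.5, 40))    # heavily skewed
        b = np.exp(rng.normal(1.0, 1.5, 40))
        est = compare_groups(a, b)
        assert est.test == "mann_whitney"
        assert est.ci_low <= est.diff <= est.ci_high

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=12),
           st.lists(st.floats(-50, 50), min_size=4, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_swapping_groups_negates_diff_and_mirrors_ci(self, a, b):
        a, b = np.round(a, 3), np.round(b, 3)
        if np.std(a) < 1e-6 or np.std(b) < 1e-6:
            return
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        assert ba.diff == pytest.approx(-ab.diff, abs=1e-9)
        assert ba.ci_low == pytest.approx(-ab.ci_high, abs=1e-9)
        assert ba.ci_high == pytest.approx(-ab.ci_low, abs=1e-9)
        assert ba.p == pytest.approx(ab.p, abs=1e-9)

    def test_degenerate_identical_constant_groups_rejected(self):
        with pytest.raises(StatsError):
            compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestCompareFromSummaries:
    def test_published_manual_opening_comparison(self):
        """Patient vs control natural opening: diff 4.20 mm, CI [1.41, 6.99]."""
        est = compare_from_summaries(25.64, 1.094, 44, 29.84, 0.7984, 37)
        assert est.diff == pytest.approx(4.20, abs=5e-3)
        assert est.se == pytest.approx(1.40, abs=5e-3)
        assert est.ci_low == pytest.approx(1.41, abs=5e-3)
        assert est.ci_high == pytest.approx(6.99, abs=5e-3)
        assert est.df == 79
        assert est.p < 0.05

    def test_published_automatic_angle_comparison(self):
        est = compare_from_summaries(15.09, 1.13, 44, 8.85, 0.78, 37)
        assert est.diff == pytest.approx(-6.24, abs=5e-3)
        assert est.se == pytest.approx(1.43, abs=5e-3)
        assert est.ci_low == pytest.approx(-9.08, abs=5e-3)
        assert est.ci_high == pytest.approx(-3.40, abs=5e-3)

    def test_equal_summaries_symmetric_about_zero(self):
        est = compare_from_summaries(10.0, 0.5, 20, 10.0, 0.5, 20)
        assert est.diff == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)
        assert est.p == pytest.approx(1.0)

    def test_simulated_groups_land_within_two_se_of_summary_diff(self):
        """Monte-Carlo sanity: raw draws at the published angle summaries."""
        ref = compare_from_summaries(15.09, 1.13, 44, 8.85, 0.78, 37)
        rng = np.random.default_rng(123)
        a = rng.normal(15.09, 1.13 * math.sqrt(44), 44)
        b = rng.normal(8.85, 0.78 * math.sqrt(37), 37)
        est = compare_groups(a, b)
        assert abs(est.diff - ref.diff) < 2 * ref.se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            compare_from_summaries(1.0, 0.0, 10, 2.0, 0.5, 10)
        with pytest.raises(StatsError):
            compare_from_summaries(float("nan"), 0.5, 10, 2.0, 0.5, 10)


class TestCompareDirections:
    def test_identical_margins_give_p_one(self):
        p, test = compare_directions(DirectionCounts(10, 10), DirectionCounts(10, 10))
        assert p == pytest.approx(1.0)
        assert test == "fisher_exact"

    def test_perfect_separation_is_extreme(self):
        p, _ = compare_directions(DirectionCounts(20, 0), DirectionCounts(0, 20))
        assert p < 1e-6

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        p, _ = compare_directions(DirectionCounts(12, 8), DirectionCounts(9, 11))
        assert p == pytest.approx(fisher_two_sided_enumeration(12, 8, 9, 11), abs=1e-12)

    def test_enumeration_agreement_on_margin_grid(self):
        """Spot grid of moderate tables: scipy backend == own enumeration."""
        for a, b, c, d in product([0, 3, 7], [2, 5], [1, 6], [0, 4, 9]):
            if (a + b) == 0 or (c + d) == 0 or (a + b + c + d) == 0:
                continue
            p, _ = compare_directions(DirectionCounts(a, b), DirectionCounts(c, d))
            assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d),
                                      abs=1e-10), (a, b, c, d)

    def test_chi_square_used_when_allowed_and_expected_counts_large(self):
        p, test = compare_directions(DirectionCounts(20, 15), DirectionCounts(12, 18),
                                     allow_chi2=True)
        assert test == "chi_square"
        assert 0 <= p <= 1

    def test_all_zero_table_rejected(self):
        with pytest.raises(StatsError):
            compare_directions(DirectionCounts(0, 0, 5), DirectionCounts(0, 0, 4))


class TestCICoverage:
    def test_95_ci_covers_true_difference_at_study_sizes(self):
        """2000 simulated pairs at n = (44, 37): coverage within 95 +/- 1.5%."""
        rng = np.random.default_rng(2026)
        true_diff = 4.2
        n_a, n_b, sd = 44, 37, 7.0
        reps = 2000
        covered = 0
        for _ in range(reps):
            a = rng.normal(25.0, sd, n_a)
            b = rng.normal(25.0 + true_diff, sd, n_b)
            sa, sb = summarize(a), summarize(b)
            est = compare_from_summaries(sa.mean, sa.sem, sa.n, sb.mean, sb.sem, sb.n)
            covered += est.ci_low <= true_diff <= est.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.015)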