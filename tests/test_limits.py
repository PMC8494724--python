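import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import visref as v
from visref import EyeStrategy, TailMode
from visref.errors import DataError, NormalityRefusal, TierRefusal

from conftest import make_bilateral


# ---------------------------------------------------------------------------
# rank arithmetic
# ---------------------------------------------------------------------------

class TestRankIndex:
    @pytest.mark.parametrize("p,n,expected", [
        (0.025, 100, 3.0),     # worked example: 3rd smallest of 100
        (0.5, 1, 1.0),         # a single point is its own median rank
        (0.975, 100, 98.0),    # mirror of the 2.5th-percentile rank
    ])
    def test_values(self, p, n, expected):
        assert v.rank_index(p, n) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            v.rank_index(p, 100)


class TestMinNForSeparation:
    @pytest.mark.parametrize("P,expected", [
        (2.5, 39),   # separating the 2.5th from the 5th percentile
        (100, 0),
        (5, 19),
    ])
    def test_values(self, P, expected):
        assert v.min_n_for_separation(P) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            v.min_n_for_separation(0)


# ---------------------------------------------------------------------------
# nonparametric quantiles
# ---------------------------------------------------------------------------

def quantile_oracle(values, p):
    """Brute-force rank-and-index oracle: sort, index 0.5 + p·n rounded
    half up, clamp to [1, n]."""
    x = sorted(values)
    n = len(x)
    k = int(np.floor(0.5 + p * n + 0.5 + 1e-9))
    return x[min(max(k, 1), n) - 1]


class TestQuantileNonparametric:
    @pytest.mark.parametrize("n_sets", [1, 2, 3, 7])
    def test_digits_tenth_percentile_is_one(self, n_sets):
        """The 10th percentile of the digits 0-9 is 1 however many sets of
        those digits are pooled."""
        digits = list(range(10)) * n_sets
        assert v.quantile_nonparametric(digits, 0.10) == 1.0

    def test_rank3_of_100(self):
        assert v.quantile_nonparametric(np.arange(1, 101), 0.025) == 3.0

    def test_median_odd_n(self, rng):
        x = rng.normal(size=21)
        assert v.quantile_nonparametric(x, 0.5) == np.sort(x)[10]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
           st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, values, p):
        assert v.quantile_nonparametric(values, p) == quantile_oracle(values, p)

    def test_empty_refused(self):
        with pytest.raises(DataError):
            v.quantile_nonparametric([], 0.5)

    def test_interpolated_between_order_stats(self):
        # rank 0.5 + 0.3*5 = 2.0 exactly -> both conventions agree
        assert v.quantile_nonparametric([1, 2, 3, 4, 5], 0.3,
                                        method="interpolated") == 2.0


# ---------------------------------------------------------------------------
# order-statistic CI
# ---------------------------------------------------------------------------

def order_ci_oracle(n, p, conf):
    """Independent exhaustive search using binomial pmf sums."""
    pmf = [stats.binom.pmf(k, n, p) for k in range(n + 1)]
    best = None
    for l in range(1, n):
        for u in range(l + 1, n + 1):
            cov = sum(pmf[l:u])  # P(l <= Y <= u-1)
            if cov >= conf:
                width = u - l
                sym = abs((l + u) / 2 - (0.5 + p * n))
                key = (width, sym)
                if best is None or key < best[0]:
                    best = (key, (l, u))
    return None if best is None else best[1]


class TestOrderStatisticCI:
    def test_reference_pair_at_120(self):
        ci = v.order_statistic_ci(120, 0.025, 0.90)
        assert (ci.lower_rank, ci.upper_rank) == (1, 7)
        assert ci.attainable and ci.coverage >= 0.90

    @pytest.mark.parametrize("n", [91, 95, 100, 120, 150])
    @pytest.mark.parametrize("p", [0.025, 0.05])
    def test_matches_exhaustive_oracle(self, n, p):
        ci = v.order_statistic_ci(n, p, 0.90)
        expected = order_ci_oracle(n, p, 0.90)
        if expected is None:
            assert not ci.attainable
        else:
            assert (ci.lower_rank, ci.upper_rank) == expected

    def test_unattainable_at_39(self):
        """At the bare minimum n=39 only the extremes estimate the limits;
        no interior pair reaches 90% coverage."""
        ci = v.order_statistic_ci(39, 0.025, 0.90)
        assert not ci.attainable

    def test_zero_confidence_always_attainable(self):
        ci = v.order_statistic_ci(11, 0.5, 0.0)
        assert ci.attainable and ci.upper_rank - ci.lower_rank == 1

    def test_smallest_attainable_n_consistent(self):
        n_min = v.smallest_attainable_n(0.025, 0.90)
        assert not v.order_statistic_ci(n_min - 1, 0.025, 0.90).attainable
        assert v.order_statistic_ci(n_min, 0.025, 0.90).attainable


# ---------------------------------------------------------------------------
# parametric CIs
# ---------------------------------------------------------------------------

class TestApproxCI:
    def test_constant_rounds_to_281(self):
        assert round(v.ci_approx_constant(0.95, 0.90), 2) == 2.81

    def test_halfwidth_values(self):
        assert v.ci_approx_halfwidth(1, 120) == pytest.approx(
            v.ci_approx_constant() / np.sqrt(120))
        assert v.ci_approx_halfwidth(0, 50) == 0.0

    def test_quarter_sample_size_doubles_halfwidth(self):
        assert v.ci_approx_halfwidth(2.0, 400) == pytest.approx(
            0.5 * v.ci_approx_halfwidth(2.0, 100))


class TestLawlessCI:
    def test_error_strictly_decreasing(self):
        hw = [abs(v.ci_approx_halfwidth(1, n) - v.ci_lawless(1, n).halfwidth)
              / v.ci_lawless(1, n).halfwidth for n in (20, 40, 80, 160)]
        assert all(a > b for a, b in zip(hw, hw[1:]))

    def test_asymptotic_agreement(self):
        n = 10**6
        law = v.ci_lawless(1.0, n)
        assert abs(v.ci_approx_halfwidth(1, n) - law.halfwidth) / law.halfwidth < 1e-5

    def test_symmetry_between_limits(self):
        law = v.ci_lawless(2.5, 60)
        assert law.lower_limit_below == law.upper_limit_above
        assert law.lower_limit_above == law.upper_limit_below


# ---------------------------------------------------------------------------
# parametric limits
# ---------------------------------------------------------------------------

class TestParametricLimits:
    def test_gaussian_consistency(self, rng):
        # allow_nonnormal: the check is about limit consistency, not the
        # normality gate (composite tests falsely reject ~5% of true
        # Gaussians at this n); the gate has its own tests
        x = rng.normal(100, 10, 10_000)
        est = v.parametric_limits(x, transform="none", allow_nonnormal=True)
        assert est.lower == pytest.approx(100 - 1.96 * 10, rel=0.02)
        assert est.upper == pytest.approx(100 + 1.96 * 10, rel=0.02)
        assert est.ci_lower[0] < est.lower < est.ci_lower[1]
        assert est.ci_upper[0] < est.upper < est.ci_upper[1]

    def test_lognormal_with_log_transform(self, rng):
        x = rng.lognormal(mean=4.0, sigma=0.3, size=4000)
        est = v.parametric_limits(x, transform="log")
        true_lo, true_hi = stats.lognorm(0.3, scale=np.exp(4.0)).ppf([0.025, 0.975])
        assert est.lower == pytest.approx(true_lo, rel=0.05)
        assert est.upper == pytest.approx(true_hi, rel=0.05)
        assert est.method == "parametric_transformed"

    def test_skewed_sample_refused_untransformed(self):
        g = v.generate_skewed_reference(500, "gamma", seed=11, shape=2, scale=1)
        with pytest.raises(NormalityRefusal):
            v.parametric_limits(g.values, transform="none")

    def test_small_sample_refused(self, rng):
        with pytest.raises(TierRefusal):
            v.parametric_limits(rng.normal(size=15))

    def test_one_tailed_upper_uses_95th(self, rng):
        x = rng.normal(100, 10, 8000)
        est = v.parametric_limits(x, transform="none", tail=TailMode.UPPER_ONLY)
        assert est.lower is None
        assert est.upper == pytest.approx(100 + 1.645 * 10, rel=0.02)
        # the uncertainty denominator stays the two-tailed interval
        assert est.ri_width == pytest.approx(2 * 1.96 * 10, rel=0.03)

    def test_backtransform_preserves_ordering(self, rng):
        x = rng.lognormal(mean=2.0, sigma=0.4, size=2000)
        est = v.parametric_limits(x, transform="auto")
        assert est.lower < est.upper
        assert est.ci_lower[0] < est.ci_lower[1]
        assert est.ci_upper[0] < est.ci_upper[1]


# ---------------------------------------------------------------------------
# eye strategies
# ---------------------------------------------------------------------------

class TestEyeStrategy:
    def test_all_bilateral_duplicate_equals_all_eyes(self, rng):
        pairs = rng.normal(size=(30, 2))
        s = make_bilateral(pairs)
        dup, _ = v.apply_eye_strategy(s, EyeStrategy.DUPLICATE)
        alle, _ = v.apply_eye_strategy(s, EyeStrategy.ALL_EYES)
        np.testing.assert_array_equal(np.sort(dup), np.sort(alle))

    def test_all_single_duplicate_preserves_quantiles(self, rng):
        singles = rng.normal(size=40)
        s = make_bilateral(list(singles))
        dup, subj = v.apply_eye_strategy(s, EyeStrategy.DUPLICATE)
        one, _ = v.apply_eye_strategy(s, EyeStrategy.ONE_EYE)
        assert len(dup) == 80
        # duplication copies each value; rank-based limits cannot move
        assert v.quantile_nonparametric(dup, 0.025) == \
            v.quantile_nonparametric(one, 0.025)

    def test_mixed_cohort_two_values_per_subject(self, rng):
        pairs = [tuple(p) for p in rng.normal(size=(30, 2))] + \
            list(rng.normal(size=10))
        s = make_bilateral(pairs)
        vals, subj = v.apply_eye_strategy(s, EyeStrategy.DUPLICATE)
        _, counts = np.unique(subj, return_counts=True)
        assert set(counts) == {2}

    def test_one_eye_prefers_right(self):
        s = make_bilateral([(1.0, 2.0), (3.0, 4.0)])
        vals, _ = v.apply_eye_strategy(s, EyeStrategy.ONE_EYE, prefer_side="R")
        np.testing.assert_array_equal(np.sort(vals), [1.0, 3.0])

    def test_three_values_per_subject_rejected(self, rng):
        s = make_bilateral([(1.0, 2.0)])
        df = s.data.copy()
        df.loc[len(df)] = df.iloc[0]
        df.loc[len(df) - 1, "side"] = "NA"
        s2 = v.ReferenceSample("b_amp", df)
        with pytest.raises(DataError):
            v.apply_eye_strategy(s2, EyeStrategy.ALL_EYES)


# ---------------------------------------------------------------------------
# bootstrap limits & CI/RI ratio
# ---------------------------------------------------------------------------

class TestBootstrapLimits:
    def test_degenerate_sample_zero_width_ci(self):
        s = make_bilateral([(5.0, 5.0)] * 45)
        est = v.bootstrap_limits(s, seed=0)
        assert est.lower == est.upper == 5.0
        assert est.ci_lower == (5.0, 5.0)
        assert est.ci_ri_ratios["lower"] == 0.0

    def test_seed_reproducible(self, rng):
        s = make_bilateral(rng.normal(size=(50, 2)))
        a = v.bootstrap_limits(s, seed=7)
        b = v.bootstrap_limits(s, seed=7)
        assert a.ci_lower == b.ci_lower and a.ci_upper == b.ci_upper

    def test_narrower_than_order_statistic_ci_on_skewed_sample(self):
        g = v.generate_skewed_reference(120, "gamma", seed=4, shape=2, scale=1)
        s = make_bilateral(list(g.values))
        boot = v.bootstrap_limits(s, strategy=EyeStrategy.ONE_EYE, seed=1)
        exact = v.nonparametric_limits(g.values)
        assert boot.ci_ri_ratios["upper"] < exact.ci_ri_ratios["upper"]

    def test_tier_refusal(self):
        s = make_bilateral([(1.0, 2.0)] * 8)
        with pytest.raises(TierRefusal):
            v.bootstrap_limits(s, seed=0)

    def test_perfect_correlation_one_eye_equals_all_eyes(self, rng):
        vals = rng.normal(size=60)
        s = make_bilateral([(x, x) for x in vals])
        a = v.bootstrap_limits(s, strategy=EyeStrategy.ONE_EYE, seed=3)
        b = v.bootstrap_limits(s, strategy=EyeStrategy.ALL_EYES, seed=3)
        assert a.lower == b.lower  # identical point estimates at r = 1
        wa = a.ci_lower[1] - a.ci_lower[0]
        wb = b.ci_lower[1] - b.ci_lower[0]
        assert wb == pytest.approx(wa, rel=0.35)  # subject bootstrap: no shrink


class TestCiRiRatio:
    def test_skewed_long_tail_has_wider_ratio(self):
        g = v.generate_skewed_reference(200, "gamma", seed=9, shape=2, scale=1)
        est = v.nonparametric_limits(g.values)
        assert est.ci_ri_ratios["upper"] > est.ci_ri_ratios["lower"]

    def test_ci_equal_to_ri_fails_flag(self):
        est = v.ReferenceLimitEstimate(
            method="nonparametric", tail=TailMode.TWO_TAILED,
            lower=0.0, upper=1.0, ci_lower=(0.0, 1.0), ci_upper=(0.5, 1.0),
            ri_width=1.0)
        ratios = v.ci_ri_ratio(est)
        assert ratios["lower"] == 1.0
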