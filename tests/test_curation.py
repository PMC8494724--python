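import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import visref as v
from visref import OutlierFlag
from visref.errors import DataError, ProtocolRefusal

from conftest import make_sample


class TestTukeyFences:
    def test_gaussian_far_fence_rate_two_per_million(self):
        rate = v.fence_exceedance(stats.norm(), multiplier=3.0)
        assert round(rate * 1e6) == 2

    def test_gamma_far_fence_rate_matches_monte_carlo(self):
        """Analytic far-fence rate for gamma(2,1) agrees with a seeded
        Monte-Carlo oracle and is of order per-thousand."""
        dist = stats.gamma(2, scale=1)
        analytic = v.fence_exceedance(dist, multiplier=3.0)
        draws = dist.rvs(size=10_000_000, random_state=np.random.default_rng(0))
        q1, q3 = dist.ppf([0.25, 0.75])
        iqr = q3 - q1
        mc = np.mean((draws > q3 + 3 * iqr) | (draws < q1 - 3 * iqr))
        assert analytic == pytest.approx(mc, rel=0.1)
        assert 1e-3 < analytic < 1e-2

    def test_all_equal_no_outliers(self):
        rep = v.tukey_fences([3.0] * 10)
        assert rep.n_flagged == 0 and rep.warnings

    def test_flags_and_policy(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), [50.0]])
        rep = v.tukey_fences(x)
        assert rep.flags[-1] is OutlierFlag.FAR
        assert rep.removal_mask().sum() == (rep.flags == OutlierFlag.FAR).sum()

    @given(st.floats(0.1, 100), st.floats(-1000, 1000))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 100), [15.0, -12.0]])
        base = v.tukey_fences(x).flags
        scaled = v.tukey_fences(a * x + b).flags
        assert list(base) == list(scaled)

    def test_too_small_rejected(self):
        with pytest.raises(DataError):
            v.tukey_fences([1, 2, 3])


class TestGrubbsAndDixon:
    def test_grubbs_recovers_injected_outlier(self, rng):
        x = np.concatenate([rng.normal(0, 1, 60), [10.0]])
        rep = v.grubbs_test(x)
        assert rep.flags[-1] is OutlierFlag.FAR
        assert (np.asarray(rep.flags[:-1]) == OutlierFlag.KEPT).all()

    def test_symmetric_three_points_unflagged(self):
        rep = v.grubbs_test([-1.0, 0.0, 1.0])
        assert rep.n_flagged == 0

    def test_gamma_sample_warns_about_normality(self):
        g = v.generate_skewed_reference(300, "gamma", seed=1, shape=2, scale=1)
        rep = v.grubbs_test(g.values)
        assert any("normality" in w for w in rep.warnings)

    def test_dixon_flags_extreme(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), [30.0]])
        rep = v.dixon_q(x)
        assert rep.flags[-1] is OutlierFlag.FAR

    def test_dixon_size_limits(self, rng):
        with pytest.raises(ProtocolRefusal):
            v.dixon_q(rng.normal(size=40))


class TestRobustLocationScale:
    def test_gaussian_recovery(self, rng):
        x = rng.normal(50, 5, 10_000)
        loc, scale = v.robust_location_scale(x)
        assert loc == pytest.approx(50, abs=3 * 5 / np.sqrt(10_000))
        assert scale == pytest.approx(5, rel=0.05)

    def test_resists_gross_contamination(self, rng):
        clean = rng.normal(0, 1, 900)
        x = np.concatenate([clean, np.full(100, 100.0)])  # 10% at +100 sigma
        loc, _ = v.robust_location_scale(x)
        assert abs(loc - 0.0) < 0.1

    def test_symmetric_pair_midpoint(self):
        loc, _ = v.robust_location_scale([1.0, 1.0, 2.0, 3.0, 3.0])
        assert loc == pytest.approx(2.0, abs=1e-6)


class TestAgeModel:
    def _aged_sample(self, rng, slope=-0.2, noise=3.0, n=300):
        age = rng.uniform(5, 80, n)
        value = 100 + slope * age + rng.normal(0, noise, n)
        return make_sample(value, age=age), age

    def test_slope_recovery(self, rng):
        s, _ = self._aged_sample(rng)
        m = v.fit_age_model(s, form="linear")
        assert m.slope_ci[0] < -0.2 < m.slope_ci[1]

    def test_age_independent_slope_ci_contains_zero(self, rng):
        s = make_sample(rng.normal(100, 3, 300), age=rng.uniform(5, 80, 300))
        m = v.fit_age_model(s, form="linear")
        assert m.slope_ci[0] < 0 < m.slope_ci[1]

    def test_adjustment_changes_outlier_flags_for_elderly(self, rng):
        """With a genuine age trend and a handful of elderly subjects,
        flagging before age adjustment erroneously singles out the elderly;
        flagging after adjustment does not."""
        age = np.r_[rng.uniform(30, 50, 190), np.full(10, 85.0)]
        value = 100 - 0.8 * age + rng.normal(0, 1.0, 200)
        s = make_sample(value, age=age)
        before = np.asarray(v.tukey_fences(s.values).flags)
        m = v.fit_age_model(s, form="linear")
        adj = v.age_adjust(s, m)
        after = np.asarray(v.tukey_fences(adj.values).flags)
        flagged_before = before != OutlierFlag.KEPT
        flagged_after = after != OutlierFlag.KEPT
        # all elderly subjects flagged pre-adjustment, none after
        assert flagged_before[190:].all()
        assert flagged_after.sum() < flagged_before.sum()
        assert not flagged_after[190:].any()

    def test_insufficient_age_spread_degrades_to_none(self, rng):
        s = make_sample(rng.normal(100, 3, 50), age=np.full(50, 30.0))
        m = v.fit_age_model(s, form="linear")
        assert m.form == "none"

    def test_missing_ages_refused(self, rng):
        ages = np.r_[rng.uniform(5, 80, 20), [np.nan] * 20]
        s = make_sample(rng.normal(100, 3, 40), age=ages)
        with pytest.raises(ProtocolRefusal):
            v.fit_age_model(s, form="linear")


class TestCurationOrderInvariants:
    def test_removing_zero_outliers_leaves_limits_identical(self, rng):
        x = rng.normal(100, 10, 200)
        rep = v.tukey_fences(x)
        assert rep.removal_mask().sum() == 0
        s = make_sample(x)
        trimmed = s.drop_rows(rep.removal_mask(), step="outliers")
        a = v.nonparametric_limits(s.values)
        b = v.nonparametric_limits(trimmed.values)
        assert (a.lower, a.upper, a.ci_lower, a.ci_upper) == \
            (b.lower, b.upper, b.ci_lower, b.ci_upper)


class TestPartitionCheck:
    def test_identical_groups_combine(self, rng):
        x = rng.normal(0, 1, 200)
        d = v.partition_check(x, x.copy())
        assert d.recommendation == "combine"

    def test_mean_gap_30pct_triggers_partition(self, rng):
        a = rng.normal(0, 1, 400)
        combined_ri = 2 * 1.96  # approx width of the pooled RI
        b = rng.normal(0.30 * combined_ri, 1, 400)
        d = v.partition_check(a, b)
        assert d.mean_rule_25pct and d.recommendation == "partition"

    def test_sd_ratio_rule_fires_with_equal_means(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 1.7, 500)
        d = v.partition_check(a, b)
        assert d.sd_ratio_rule and d.recommendation == "partition"

    def test_small_groups_refused(self, rng):
        with pytest.raises(ProtocolRefusal):
            v.partition_check(rng.normal(size=10), rng.normal(size=30))
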