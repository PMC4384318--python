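import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ampcnv import (
    copy_number,
    dispersion_factor,
    effective_n,
    p_score,
    q_score,
    remove_outliers,
    standard_error,
    weighted_mean,
    weighted_variance,
)
from ampcnv.cluster_stats import compute_statistics
from ampcnv.cluster_stats import test_cluster as weighted_t_test
from conftest import make_cluster

# Reference values computed with R 4.3 (qt/pt), frozen:
QT_975_DF9 = 2.2621571627982  # qt(0.975, 9)
P_T3_DF9 = 0.0149563639104142  # 2*pt(-3, 9)
QT_975_DF2_5 = 3.57465484200369  # qt(0.975, 2.5) — fractional df
P_T22_DF6_4 = 0.0673081568071609  # 2*pt(-2.2, 6.4) — fractional df


def brute_mean(x, w):
    return sum(wi * xi for wi, xi in zip(w, x)) / sum(w)


def brute_var(x, w):
    mu = brute_mean(x, w)
    return sum(wi * (xi - mu) ** 2 for wi, xi in zip(w, x)) / (sum(w) - 1)


def brute_neff(w):
    return sum(w) ** 2 / sum(wi**2 for wi in w)


class TestMoments:
    def test_equal_weights_reduce_to_arithmetic_mean(self):
        assert weighted_mean([1, 2, 3], [5, 5, 5]) == pytest.approx(2.0)

    def test_weighted_mean_small_example(self):
        assert weighted_mean([1, 3], [1, 3]) == pytest.approx(2.5)

    def test_constant_data(self):
        assert weighted_mean([4.2] * 5, [1, 2, 3, 4, 5]) == pytest.approx(4.2)
        assert weighted_variance([4.2] * 5, [10, 20, 30, 40, 50]) == pytest.approx(0.0)

    def test_variance_small_example(self):
        # two points at 0 and 1, unit weights: W=2, each deviation 0.25
        assert weighted_variance([0, 1], [1, 1]) == pytest.approx(0.5)

    def test_variance_depends_on_weight_scale(self):
        # count-based weights: scaling w by k changes the W-1 denominator
        x = [0.1, -0.2, 0.3, 0.05]
        w = [10.0, 20.0, 15.0, 5.0]
        k = 10.0
        expected_ratio = k * (sum(w) - 1) / (k * sum(w) - 1)
        got = weighted_variance(x, [k * wi for wi in w]) / weighted_variance(x, w)
        assert got == pytest.approx(expected_ratio, rel=1e-12)

    @pytest.mark.parametrize("w,expected", [([1] * 10, 10.0), ([1, 1, 2], 16 / 6), ([7.0], 1.0)])
    def test_effective_n_examples(self, w, expected):
        assert effective_n(w) == pytest.approx(expected, rel=1e-12)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])
        with pytest.raises(ValueError):
            weighted_mean([1.0], [0.0])
        with pytest.raises(ValueError):
            weighted_variance([0, 1], [0.4, 0.5])  # W <= 1

    @settings(deadline=None, max_examples=200)
    @given(
        data=st.lists(
            st.tuples(st.floats(-5, 5), st.floats(0.01, 1e4)), min_size=2, max_size=50
        )
    )
    def test_moments_match_bruteforce(self, data):
        x = [d[0] for d in data]
        w = [d[1] for d in data]
        if sum(w) <= 1:
            w = [wi + 1 for wi in w]
        assert weighted_mean(x, w) == pytest.approx(brute_mean(x, w), rel=1e-9, abs=1e-10)
        assert weighted_variance(x, w) == pytest.approx(brute_var(x, w), rel=1e-9, abs=1e-10)
        assert effective_n(w) == pytest.approx(brute_neff(w), rel=1e-12)
        assert 0 < effective_n(w) <= len(w) + 1e-9


class TestStandardError:
    def test_zero_dispersion(self):
        assert standard_error(0.0, 10.0) == 0.0

    def test_matches_r_quantile_integer_df(self):
        assert standard_error(0.5, 10.0, 0.05) == pytest.approx(
            QT_975_DF9 * 0.5 / math.sqrt(10), rel=1e-12
        )

    def test_fractional_df_matches_r(self):
        assert standard_error(1.0, 3.5, 0.05) == pytest.approx(
            QT_975_DF2_5 * 1.0 / math.sqrt(3.5), rel=1e-10
        )

    def test_normal_limit(self):
        se = standard_error(1.0, 1e7, 0.05)
        assert se == pytest.approx(1.959964 / math.sqrt(1e7), rel=1e-4)

    def test_requires_nstar_above_one(self):
        with pytest.raises(ValueError):
            standard_error(0.5, 1.0)


class TestTTest:
    def test_null_case(self):
        t, p = weighted_t_test([0.0, 0.0, 0.1, -0.1], [1, 1, 1, 1], mu0=0.0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetry_under_negation(self):
        x = [0.3, 0.5, 0.2, 0.4, 0.35]
        w = [100, 200, 150, 120, 180]
        t1, p1 = weighted_t_test(x, w)
        t2, p2 = weighted_t_test([-v for v in x], w)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_known_t_and_p_against_r(self):
        # mu*=0.5, sigma_w=0.5, n*=9 gives t = sqrt(9)*0.5/0.5 = 3 and
        # p = 2*pt(-3, df=9); the tail probability is checked against R
        n_star = 9.0
        t = math.sqrt(n_star) * 0.5 / 0.5
        assert t == pytest.approx(3.0)
        assert 2 * sps.t.cdf(-3.0, df=9) == pytest.approx(P_T3_DF9, rel=1e-12)

    def test_fractional_df_p_matches_r(self):
        assert 2 * sps.t.cdf(-2.2, df=6.4) == pytest.approx(P_T22_DF6_4, rel=1e-12)

    def test_zero_variance_conventions(self):
        t, p = weighted_t_test([0.5, 0.5, 0.5], [1, 2, 3], mu0=0.0)
        assert math.isinf(t) and t > 0 and p == 0.0
        t, p = weighted_t_test([0.0, 0.0, 0.0], [1, 2, 3], mu0=0.0)
        assert t == 0.0 and p == 1.0

    @settings(deadline=None, max_examples=100)
    @given(x=st.lists(st.floats(-2, 2), min_size=3, max_size=30))
    def test_unit_weights_degenerate_to_classic_t_test(self, x):
        """With w_i = 1 for all i the weighted chain collapses to the textbook
        one-sample t statistic (W = n, sigma_w = sample SD, n* = n); the
        p-value is the two-sided tail with df = n by definition."""
        if np.ptp(x) < 1e-6:
            return
        n = len(x)
        w = [1.0] * n
        t_classic = float(sps.ttest_1samp(np.asarray(x), 0.0).statistic)
        t, p = weighted_t_test(x, w)
        assert effective_n(w) == pytest.approx(n, rel=1e-12)
        assert t == pytest.approx(t_classic, rel=1e-9)
        assert p == pytest.approx(2 * sps.t.cdf(-abs(t_classic), df=n), rel=1e-9)


class TestScores:
    @pytest.mark.parametrize(
        "sigma_w,mu,expected", [(1.0, 0.0, 1.0), (0.25, 1.0, 1.0), (0.0, 3.0, 0.0)]
    )
    def test_dispersion_factor(self, sigma_w, mu, expected):
        assert dispersion_factor(sigma_w, mu) == pytest.approx(expected)

    def test_dispersion_factor_monotone_in_effect_size(self):
        phis = [dispersion_factor(0.3, m) for m in np.linspace(0, 3, 10)]
        assert all(b > a for a, b in zip(phis, phis[1:]))

    @pytest.mark.parametrize(
        "p,phi,expected", [(1.0, 7.0, 0.0), (0.1, 1.0, 10.0), (1e-6, 0.8, 48.0)]
    )
    def test_q_score_examples(self, p, phi, expected):
        assert q_score(p, phi) == pytest.approx(expected)

    def test_q_monotone_decreasing_in_p(self):
        qs = [q_score(p, 0.5) for p in np.logspace(-8, 0, 20)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_q_underflow_clamped_finite(self):
        q = q_score(0.0, 1.0)
        assert math.isfinite(q) and q > 3000

    @pytest.mark.parametrize(
        "se,expected", [(1.0, 0.0), (math.exp(-3), 30.0), (math.exp(-2), 20.0)]
    )
    def test_p_score_examples(self, se, expected):
        assert p_score(se) == pytest.approx(expected)

    def test_p_score_undefined_for_nonpositive_se(self):
        assert p_score(0.0) is None


class TestCopyNumber:
    @pytest.mark.parametrize(
        "mu,se,nc,expected",
        [(0.0, 0.0, 2, 2.0), (1.0, 0.1, 2, 4.0), (-1.0, 0.1, 2, 1.0), (0.0, 0.0, 1, 1.0)],
    )
    def test_point_estimates(self, mu, se, nc, expected):
        est = copy_number(mu, se, nc)
        assert est.n_sample == pytest.approx(expected)
        assert est.n_min <= est.n_sample <= est.n_max

    def test_bounds_are_log_symmetric(self):
        est = copy_number(0.5, 0.2, 2)
        assert est.n_max / est.n_sample == pytest.approx(est.n_sample / est.n_min)

    def test_zero_control_copies_rejected(self):
        with pytest.raises(ValueError):
            copy_number(0.0, 0.0, 0)


class TestOutlierRemoval:
    def test_normal_data_untouched(self, rng):
        # fixture chosen after verifying Shapiro-Wilk accepts it
        x = rng.normal(0, 0.1, size=30)
        assert sps.shapiro(x).pvalue > 0.05
        cluster = make_cluster(x)
        remove_outliers(cluster)
        assert cluster.n_kept == 30

    def test_single_planted_extreme_removed(self, rng):
        x = np.append(rng.normal(0, 0.1, size=20), 5.0)
        assert sps.shapiro(x).pvalue <= 0.05  # rejected before
        cluster = make_cluster(x)
        remove_outliers(cluster)
        assert cluster.n_kept == 20
        assert all(p.x < 1 for p in cluster.kept)  # the 5.0 went
        assert sps.shapiro([p.x for p in cluster.kept]).pvalue > 0.05  # accepted after

    def test_one_third_cap(self, rng):
        # 9 points, 5 planted extremes: at most floor(9/3)=3 may be removed
        # extremes chosen so Shapiro-Wilk still rejects after each removal
        x = np.concatenate([rng.normal(0, 0.05, size=4), [5, 50, 500, 5000, 50000]])
        cluster = make_cluster(x)
        remove_outliers(cluster)
        assert cluster.n_kept == 6

    def test_order_and_identity_preserved(self, rng):
        x = np.append(rng.normal(0, 0.1, size=20), 5.0)
        cluster = make_cluster(x)
        remove_outliers(cluster)
        positions = [p.site.pos for p in cluster.kept]
        assert positions == sorted(positions)
        assert all(p in cluster.members for p in cluster.kept)

    def test_tiny_cluster_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(make_cluster([0.0, 0.1]))

    def test_removal_criterion_uses_weighted_mean(self):
        # weights drag mu* toward +0.4, so -0.6 is farther than +1.0 from mu*
        x = [0.4, 0.4, 0.4, 0.4, 0.4, 0.4, -0.6, 1.0, 0.41, 0.39, 0.38, 0.42]
        w = [5000, 5000, 5000, 5000, 5000, 5000, 10, 10, 5000, 5000, 5000, 5000]
        mu = weighted_mean(x, w)
        assert abs(-0.6 - mu) > abs(1.0 - mu)
        cluster = make_cluster(x, w)
        remove_outliers(cluster)
        removed = [p.x for p in cluster.members if p not in cluster.kept]
        if removed:  # SW must reject for any removal to happen
            assert removed[0] == -0.6


class TestAntisymmetry:
    def test_swapping_sample_and_control(self, rng):
        """Swapping the roles negates mu* and t, preserves p, variance, n*,
        phi and Q, and maps N_S to N_C^2/N_S."""
        x = rng.normal(0.4, 0.15, size=25)
        w = rng.integers(500, 4000, size=25).astype(float)
        c1 = make_cluster(x, w)
        c2 = make_cluster(-x, w)
        s1 = compute_statistics(c1)
        s2 = compute_statistics(c2)
        assert s2.mu_star == pytest.approx(-s1.mu_star)
        assert s2.t_stat == pytest.approx(-s1.t_stat)
        assert s2.p_value == pytest.approx(s1.p_value)
        assert s2.sigma_w2 == pytest.approx(s1.sigma_w2)
        assert s2.n_star == pytest.approx(s1.n_star)
        assert s2.phi == pytest.approx(s1.phi)
        assert s2.q_score == pytest.approx(s1.q_score)
        e1 = copy_number(s1.mu_star, s1.se, 2)
        e2 = copy_number(s2.mu_star, s2.se, 2)
        assert e2.n_sample == pytest.approx(4.0 / e1.n_sample)
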