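"""Unit and property tests for the statistical kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import gammaln

from phacksim import (
    ExperimentOutcome,
    ParameterError,
    InvalidInputError,
    TestConfig,
    analytic_fpr,
    classify_outcome,
    critical_t,
    experiment_probability,
    noncentrality,
    prior_from_scale,
    sample_effect_sizes,
    sample_t_statistics,
    scale_from_prior,
    sidak_alpha,
)


class TestExperimentProbability:
    @pytest.mark.parametrize(
        "effort, emin, eta, expected",
        [
            (5, 5, 0.01, 1.0),                 # at the effort floor
            (105, 5, 0.01, math.exp(-1)),      # exponent exactly -1
            (20, 5, 0.0, 1.0),                 # eta=0 disables the effort cost
        ],
    )
    def test_closed_form(self, effort, emin, eta, expected):
        assert experiment_probability(effort, emin, eta) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_effort(self):
        efforts = np.linspace(5, 500, 100)
        p = experiment_probability(efforts, 5, 0.01)
        assert np.all(np.diff(p) < 0)
        assert p[0] == 1.0

    @pytest.mark.parametrize("bad", [dict(effort=4, effort_min=5, eta=0.01),
                                     dict(effort=10, effort_min=5, eta=-0.1)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ParameterError):
            experiment_probability(bad["effort"], bad["effort_min"], bad["eta"])


class TestEffectSizePrior:
    def test_published_scale_value(self):
        # d_min=0.2 with an 80% prior null pins the exponential scale at 0.1243
        assert scale_from_prior(0.2, 0.8) == pytest.approx(0.1243, abs=5e-5)

    def test_scale_at_prior_one_minus_exp_minus_one(self):
        assert scale_from_prior(0.2, 1 - math.exp(-1)) == pytest.approx(0.2, rel=1e-12)

    @pytest.mark.parametrize("dmin, d0, expected, tol", [
        (0.0, 0.1243, 0.0, 1e-12),
        (0.2, 0.1243, 0.8, 5e-4),
        (0.2, 0.2 / math.log(2), 0.5, 1e-12),
    ])
    def test_prior_from_scale(self, dmin, d0, expected, tol):
        assert prior_from_scale(dmin, d0) == pytest.approx(expected, abs=tol)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, prior, dmin):
        assert prior_from_scale(dmin, scale_from_prior(dmin, prior)) == pytest.approx(prior, rel=1e-10)

    @pytest.mark.parametrize("call", [
        lambda: scale_from_prior(0.2, 0.0),
        lambda: scale_from_prior(0.2, 1.0),
        lambda: scale_from_prior(-0.1, 0.5),
        lambda: prior_from_scale(0.2, 0.0),
        lambda: prior_from_scale(0.2, -1.0),
    ])
    def test_invalid_parameters(self, call):
        with pytest.raises(ParameterError):
            call()


class TestSampleEffectSizes:
    def test_mean_and_null_mass(self, rng):
        # law-of-large-numbers check of the mean, and of the exponential
        # CDF at d_min (which is the prior probability of the null)
        scale = scale_from_prior(0.2, 0.8)
        draws = sample_effect_sizes(scale, 1_000_000, rng)
        assert np.all(draws >= 0)
        assert draws.mean() == pytest.approx(scale, abs=3 * scale / 1000)
        frac_null = np.mean(draws <= 0.2)
        se = math.sqrt(0.8 * 0.2 / draws.size)
        assert frac_null == pytest.approx(0.8, abs=max(3 * se, 0.002))

    def test_seeded_determinism(self):
        a = sample_effect_sizes(0.1243, 3, np.random.default_rng(42))
        b = sample_effect_sizes(0.1243, 3, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_invalid_k(self, rng):
        with pytest.raises(ParameterError):
            sample_effect_sizes(0.1, 0, rng)


class TestNoncentrality:
    @pytest.mark.parametrize("d, effort, expected", [
        (0.0, 20, 0.0),
        (0.2, 50, 1.0),
        (0.5, 20, 0.5 * math.sqrt(10)),
    ])
    def test_closed_form(self, d, effort, expected):
        assert noncentrality(d, effort) == pytest.approx(expected, rel=1e-12)

    def test_rejects_degenerate_effort(self):
        with pytest.raises(ParameterError):
            noncentrality(0.2, 1.0)


class TestSampleTStatistics:
    def test_type_one_calibration_under_the_null(self, rng):
        # lambda=0 must give a central t: two-sided rejection at alpha=0.05
        n = 100_000
        t = sample_t_statistics(np.zeros(n), 38, rng)
        rej = np.mean(np.abs(t) > critical_t(0.05, 38))
        se = math.sqrt(0.05 * 0.95 / n)
        assert rej == pytest.approx(0.05, abs=3 * se)

    def test_closed_form_mean(self, rng):
        # E[T] = lambda * sqrt(df/2) * Gamma((df-1)/2) / Gamma(df/2)
        lam, df, n = 1.0, 98, 1_000_000
        t = sample_t_statistics(np.full(n, lam), df, rng)
        expected = lam * math.sqrt(df / 2) * math.exp(gammaln((df - 1) / 2) - gammaln(df / 2))
        assert t.mean() == pytest.approx(expected, abs=3 * t.std(ddof=1) / math.sqrt(n))

    def test_tail_probabilities_match_nct_cdf(self, rng):
        lam, df, n = 1.5, 38, 200_000
        t = sample_t_statistics(np.full(n, lam), df, rng)
        for ref in (0.5, 1.5, 3.0):
            expected = sps.nct.sf(ref, df, lam)
            assert np.mean(t > ref) == pytest.approx(expected, abs=0.005)

    def test_power_monotone_in_effort_and_effect(self, rng):
        # rejection probability rises with effort at fixed d, and with d
        # at fixed effort (3 Monte-Carlo SE slack at 1e5 draws each)
        n = 100_000

        def reject_rate(d, effort):
            df = 2 * effort - 2
            lam = noncentrality(d, effort)
            t = sample_t_statistics(np.full(n, lam), df, rng)
            return np.mean(np.abs(t) > critical_t(0.05, df))

        slack = 3 * math.sqrt(0.25 / n)
        by_effort = [reject_rate(0.3, e) for e in (10, 20, 50, 100)]
        assert np.all(np.diff(by_effort) > -slack)
        by_effect = [reject_rate(d, 20) for d in (0.0, 0.2, 0.5, 1.0)]
        assert np.all(np.diff(by_effect) > -slack)

    def test_invalid_df(self, rng):
        with pytest.raises(ParameterError):
            sample_t_statistics([1.0], 0, rng)


class TestCriticalT:
    def test_one_sided_median(self):
        assert critical_t(0.5, 17, two_sided=False) == pytest.approx(0.0, abs=1e-12)

    def test_standard_table_value(self):
        assert critical_t(0.05, 38, two_sided=True) == pytest.approx(2.0244, abs=5e-5)

    @pytest.mark.parametrize("df", [2, 10, 38, 98.5, 400])
    def test_stricter_alpha_gives_larger_critical_value(self, df):
        assert critical_t(0.005, df) > critical_t(0.05, df)

    def test_invalid(self):
        with pytest.raises(ParameterError):
            critical_t(0.0, 10)
        with pytest.raises(ParameterError):
            critical_t(0.05, -1)


class TestSidak:
    @pytest.mark.parametrize("alpha, k, expected, tol", [
        (0.05, 1, 0.05, 1e-15),
        (0.05, 10, 1 - 0.95 ** 0.1, 1e-12),
        (0.005, 5, 1 - 0.995 ** 0.2, 1e-12),
    ])
    def test_closed_form(self, alpha, k, expected, tol):
        assert sidak_alpha(alpha, k) == pytest.approx(expected, abs=tol)

    @given(st.floats(0.001, 0.5), st.integers(2, 100))
    @settings(max_examples=100, deadline=None)
    def test_strictly_below_alpha_and_decreasing(self, alpha, k):
        a_k = sidak_alpha(alpha, k)
        assert a_k < alpha
        assert sidak_alpha(alpha, k + 1) < a_k

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_family_wise_error_is_restored(self, rng, k):
        # k independent tests at the corrected level reject as a family
        # at rate alpha (brute-force simulation oracle)
        alpha, df, n_fam = 0.05, 38, 100_000
        t_corr = critical_t(sidak_alpha(alpha, k), df)
        t = sample_t_statistics(np.zeros(n_fam * k), df, rng).reshape(n_fam, k)
        fwer = np.mean(np.any(np.abs(t) > t_corr, axis=1))
        se = math.sqrt(alpha * (1 - alpha) / n_fam)
        assert fwer == pytest.approx(alpha, abs=3 * se)

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            sidak_alpha(0.05, 0)


class TestClassifyOutcome:
    CFG = TestConfig(alpha=0.05, two_sided=True, dmin=0.2, prior_null=0.8)

    def test_clear_true_positive(self):
        out = classify_outcome([8.0], [0.5], self.CFG, df=38)
        assert out.published and out.true_positive

    def test_significant_null_effect_is_false_positive(self):
        # the null is rejected but the underlying effect is below d_min
        out = classify_outcome([2.5], [0.1], self.CFG, df=38)
        assert out.published and not out.true_positive

    def test_nothing_significant_is_unpublished(self):
        out = classify_outcome([0.5, -0.3, 1.1], [0.5, 0.1, 0.3], self.CFG, df=38)
        assert not out.published and not out.true_positive

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_outcome([1.0, 2.0], [0.1], self.CFG, df=38)
        with pytest.raises(InvalidInputError):
            classify_outcome([1.0, 2.0], [0.1, 0.2], self.CFG, df=38, k=3)

    def _brute_force(self, t_values, effect_sizes, cfg, df):
        # independent naive re-implementation: loop over tests one by one
        k = len(t_values)
        t_crit = sps.t.ppf(1 - cfg.alpha / 2, df)
        a_corr = 1 - (1 - cfg.alpha) ** (1.0 / k)
        t_crit_corr = sps.t.ppf(1 - a_corr / 2, df)
        published = False
        true_positive = False
        for t, d in zip(t_values, effect_sizes):
            if abs(t) > t_crit:
                published = True
            if abs(t) > t_crit_corr and d >= cfg.dmin:
                true_positive = True
        return published, true_positive

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        cfg = self.CFG
        for _ in range(10_000):
            k = int(rng.integers(1, 11))
            d = rng.exponential(0.1243, size=k)
            df = float(rng.uniform(8, 200))
            lam = d * math.sqrt((df / 2 + 1) / 2)
            t = sample_t_statistics(lam, df, rng)
            out = classify_outcome(t, d, cfg, df=df, k=k)
            assert (out.published, out.true_positive) == self._brute_force(t, d, cfg, df)
            assert out.true_positive <= out.published

    def test_outcome_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            ExperimentOutcome(published=False, true_positive=True, n_tests=1,
                              effect_sizes=[0.5], t_values=[3.0])


class TestTestConfig:
    def test_derives_scale_from_prior(self):
        cfg = TestConfig(dmin=0.2, prior_null=0.8)
        assert cfg.d0 == pytest.approx(0.1243, abs=5e-5)

    def test_derives_prior_from_scale(self):
        cfg = TestConfig(dmin=0.2, d0=0.2 / math.log(2))
        assert cfg.prior_null == pytest.approx(0.5, rel=1e-12)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ParameterError):
            TestConfig(dmin=0.2, prior_null=0.8, d0=0.5)


class TestAnalyticFPR:
    def test_threshold_change_published_values(self):
        # 1:10 prior odds of the alternative and power 1.0: 33% at
        # alpha=0.05 drops to 5% at alpha=0.005
        assert round(100 * analytic_fpr(0.05, 1.0, 0.1)) == 33
        assert round(100 * analytic_fpr(0.005, 1.0, 0.1)) == 5

    def test_vanishes_as_odds_grow(self):
        assert analytic_fpr(0.05, 1.0, 1e9) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_odds(self):
        with pytest.raises(ParameterError):
            analytic_fpr(0.05, 1.0, 0.0)
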