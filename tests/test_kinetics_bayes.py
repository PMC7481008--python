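"""Bayesian rate inference: sufficient statistics, posteriors, odds ratios."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from mdinfer import (
    TrajectoryOutcome,
    TransitionData,
    bayes_factor,
    credible_interval,
    interpret_bayes_factor,
    posterior,
    sufficient_statistics,
)


class TestSufficientStatistics:
    def test_observed_plus_censored(self, fig10_pair):
        a, b = fig10_pair
        assert sufficient_statistics(a + b) == (1, pytest.approx(1.466))

    def test_all_censored(self):
        data = TransitionData.from_times(censored_times=[1.0] * 5)
        assert sufficient_statistics(data) == (0, pytest.approx(5.0))

    @given(
        obs=st.lists(st.floats(0.01, 10.0), max_size=8),
        cens=st.lists(st.floats(0.01, 10.0), max_size=8),
        obs2=st.lists(st.floats(0.01, 10.0), max_size=8),
        cens2=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8),
    )
    def test_additive_under_pooling(self, obs, cens, obs2, cens2):
        if not obs and not cens:
            cens = [1.0]
        a = TransitionData.from_times(obs, cens)
        b = TransitionData.from_times(obs2, cens2)
        na, ta = sufficient_statistics(a)
        nb, tb = sufficient_statistics(b)
        n, t = sufficient_statistics(a + b)
        assert n == na + nb
        assert t == pytest.approx(ta + tb)

    def test_outcome_validation(self):
        with pytest.raises(ValueError):
            TrajectoryOutcome(True, 2.0, 1.0)  # event after trajectory end
        with pytest.raises(ValueError):
            TrajectoryOutcome(False, 0.5, 1.0)  # censored with event time
        with pytest.raises(ValueError):
            TransitionData([])


class TestPosterior:
    @pytest.mark.parametrize(
        "n, theta, prior, mean, var",
        [
            (0, 1.0, "uniform", 1.0, 1.0),
            (1, 1.466, "uniform", 2 / 1.466, 2 / 1.466**2),
            (10, 10.0, "uniform", 1.1, 0.11),
            (10, 10.0, "jeffreys", 1.0, 0.1),
        ],
    )
    def test_closed_form_moments(self, n, theta, prior, mean, var):
        data = TransitionData.from_times([theta / n] * n if n else [], [] if n else [theta])
        # construct data with the requested sufficient statistics
        if n:
            data = TransitionData.from_times([theta / n] * n)
        post = posterior(data, prior)
        assert post.mean == pytest.approx(mean)
        assert post.variance == pytest.approx(var)

    def test_pdf_normalized(self):
        for n, theta in [(0, 1.0), (3, 2.5), (40, 17.0)]:
            data = (
                TransitionData.from_times([theta / n] * n)
                if n
                else TransitionData.from_times(censored_times=[theta])
            )
            post = posterior(data, "uniform")
            total, _ = integrate.quad(post.pdf, 0, np.inf)
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_jeffreys_requires_observed_event(self):
        data = TransitionData.from_times(censored_times=[1.0, 1.0])
        with pytest.raises(ValueError, match="at least one barrier crossing"):
            posterior(data, "jeffreys")

    def test_priors_converge_with_evidence(self):
        """Total-variation distance between the two posteriors shrinks
        monotonically as transitions accumulate at a fixed true rate."""
        k_true = 2.0
        tv = []
        for n in range(1, 21):
            theta = n / k_true
            data = TransitionData.from_times([theta / n] * n)
            pu = posterior(data, "uniform")
            pj = posterior(data, "jeffreys")
            dist, _ = integrate.quad(
                lambda k: abs(pu.pdf(k) - pj.pdf(k)), 0, np.inf, limit=200
            )
            tv.append(0.5 * dist)
        assert all(a > b for a, b in zip(tv[:-1], tv[1:]))


class TestCredibleInterval:
    def test_no_transition_exponential_quantiles(self):
        data = TransitionData.from_times(censored_times=[1.0])
        post = posterior(data, "uniform")
        lo, hi = credible_interval(post, 0.95)
        assert lo == pytest.approx(-math.log(0.975))
        assert hi == pytest.approx(-math.log(0.025))

    def test_nested_levels_widen(self):
        data = TransitionData.from_times([0.3, 0.6, 0.9])
        post = posterior(data, "uniform")
        widths = [np.diff(credible_interval(post, lv))[0] for lv in (0.5, 0.8, 0.95, 0.99)]
        assert all(a < b for a, b in zip(widths[:-1], widths[1:]))

    def test_normal_limit_large_n(self):
        n, theta = 100, 100.0
        data = TransitionData.from_times([theta / n] * n)
        post = posterior(data, "uniform")
        lo, hi = credible_interval(post, 0.95)
        approx = 1.96 * math.sqrt(n + 1) / theta
        assert lo == pytest.approx(post.mean - approx, rel=0.05)
        assert hi == pytest.approx(post.mean + approx, rel=0.05)

    def test_hpd_narrower_than_central(self):
        data = TransitionData.from_times([0.2, 0.9])
        post = posterior(data, "uniform")
        c_lo, c_hi = credible_interval(post, 0.95, method="central")
        h_lo, h_hi = credible_interval(post, 0.95, method="hpd")
        assert (h_hi - h_lo) <= (c_hi - c_lo) + 1e-12

    def test_level_validation(self):
        data = TransitionData.from_times([1.0])
        post = posterior(data, "uniform")
        with pytest.raises(ValueError):
            credible_interval(post, 1.5)


class TestBayesFactor:
    def test_single_trajectory_comparison(self, fig10_pair):
        a, b = fig10_pair
        result = bayes_factor(a, b)
        assert result.odds_two_processes == pytest.approx(0.93, abs=0.005)
        assert result.label == "barely worth mentioning"
        assert result.pooled == (1, pytest.approx(1.466))

    def test_tripled_observations_cross_threshold(self, fig10_pair):
        a, b = fig10_pair
        a3 = TransitionData.from_times([0.466] * 3)
        b3 = TransitionData.from_times(censored_times=[1.0] * 3)
        assert bayes_factor(a3, b3).odds_two_processes > 3.0

    def test_identical_large_datasets_favour_one_process(self):
        data = TransitionData.from_times([1.0] * 20)
        assert bayes_factor(data, data).odds_two_processes < 1.0

    def test_large_counts_no_overflow(self):
        a = TransitionData.from_times([0.5] * 500)
        b = TransitionData.from_times([0.5] * 400)
        odds = bayes_factor(a, b).odds_two_processes
        assert np.isfinite(odds) and odds > 0

    @given(
        n1=st.integers(0, 50),
        n2=st.integers(0, 50),
        t1=st.floats(0.1, 100.0),
        t2=st.floats(0.1, 100.0),
    )
    def test_symmetry_under_swap(self, n1, n2, t1, t2):
        if n1 + n2 == 0:
            n1 = 1
        a = (
            TransitionData.from_times([t1 / n1] * n1)
            if n1
            else TransitionData.from_times(censored_times=[t1])
        )
        b = (
            TransitionData.from_times([t2 / n2] * n2)
            if n2
            else TransitionData.from_times(censored_times=[t2])
        )
        ab = bayes_factor(a, b).odds_two_processes
        ba = bayes_factor(b, a).odds_two_processes
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_no_events_anywhere_rejected(self):
        a = TransitionData.from_times(censored_times=[1.0])
        with pytest.raises(ValueError):
            bayes_factor(a, a)


class TestInterpretation:
    @pytest.mark.parametrize(
        "odds, label",
        [
            (0.26, "substantial evidence for one process"),
            (1.0, "barely worth mentioning"),
            (8.3, "substantial evidence for two processes"),
            (1 / 3, "barely worth mentioning"),
            (3.0, "barely worth mentioning"),
        ],
    )
    def test_jeffreys_scale(self, odds, label):
        assert interpret_bayes_factor(odds) == label

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            interpret_bayes_factor(0.0)


def test_coverage_of_credible_interval():
    """95% uniform-prior intervals cover the true rate at close to the
    nominal frequency over many censored synthetic datasets."""
    from mdinfer import gen_transition_data

    k_true, n_sets = 2.0, 400
    hits = 0
    for i in range(n_sets):
        data = gen_transition_data(k_true, 20, 1.0, seed=10_000 + i)
        lo, hi = posterior(data, "uniform").interval(0.95)
        hits += lo <= k_true <= hi
    assert hits / n_sets == pytest.approx(0.95, abs=0.035)


def test_posterior_matches_scipy_gamma():
    """The analytic posterior is the Gamma(n+1, theta) density."""
    data = TransitionData.from_times([0.2, 0.5, 0.9], censored_times=[1.0, 1.0])
    post = posterior(data, "uniform")
    k = np.linspace(0.01, 10, 50)
    np.testing.assert_allclose(
        post.pdf(k), stats.gamma.pdf(k, a=4, scale=1 / data.theta), rtol=1e-12
    )
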