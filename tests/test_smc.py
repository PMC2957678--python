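"""Bayesian sequential hypothesis testing: closed forms, stopping, errors."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import betaln

from hmgb1smc.fixtures import make_bernoulli_sampler, make_toy_network
from hmgb1smc.smc import (
    HypothesisTestSpec,
    bayes_factor,
    error_bound,
    smc_decide,
    verify_property,
)


def quadrature_beta_cdf(a: float, b: float, theta: float) -> float:
    """Independent oracle: numerically integrate the Beta density."""
    lognorm = betaln(a, b)

    def density(t):
        return np.exp((a - 1) * np.log(t) + (b - 1) * np.log1p(-t) - lognorm)

    val, _ = integrate.quad(density, 0.0, theta, epsabs=1e-13, epsrel=1e-13)
    return val


class TestBayesFactor:
    def test_uniform_prior_no_data(self):
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=1000)
        # F_(1,1)(theta) = theta, so B = 1/0.9 - 1
        assert bayes_factor(0, 0, spec) == pytest.approx(1 / 0.9 - 1)

    def test_single_failure_half_threshold(self):
        spec = HypothesisTestSpec(theta=0.5, bayes_threshold=1000)
        # F_(1,2)(0.5) = 1 - 0.25 = 0.75 -> B = 1/3
        assert bayes_factor(0, 1, spec) == pytest.approx(1 / 3)

    def test_sixty_five_successes_cross_thousand(self):
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=1000)
        # F_(66,1)(0.9) = 0.9^66 (closed-form power oracle)
        expected = 1 / 0.9**66 - 1
        assert bayes_factor(65, 65, spec) == pytest.approx(expected)
        assert bayes_factor(65, 65, spec) > 1000
        assert bayes_factor(64, 64, spec) < 1000

    def test_matches_quadrature_oracle_on_grid(self):
        for theta in (0.1, 0.3, 0.5, 0.7, 0.9):
            for alpha in (0.5, 1.0, 2.0):
                for beta in (0.5, 1.0, 2.0):
                    spec = HypothesisTestSpec(
                        theta=theta, bayes_threshold=1000, alpha=alpha, beta=beta
                    )
                    for n in (0, 1, 3, 10, 50):
                        for x in {0, 1, n // 2, n}:
                            if x > n:
                                continue
                            F = quadrature_beta_cdf(x + alpha, n - x + beta, theta)
                            expected = 1.0 / F - 1.0
                            got = bayes_factor(x, n, spec)
                            assert got == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_successes_and_threshold(self):
        spec = HypothesisTestSpec(theta=0.7, bayes_threshold=1000)
        n = 30
        values = [bayes_factor(x, n, spec) for x in range(n + 1)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        by_theta = [
            bayes_factor(20, n, HypothesisTestSpec(theta=t, bayes_threshold=1000))
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(b <= a for a, b in zip(by_theta, by_theta[1:]))

    def test_invalid_counts_rejected(self):
        spec = HypothesisTestSpec()
        with pytest.raises(ValueError):
            bayes_factor(5, 3, spec)


class TestSequentialDecision:
    def test_accepts_after_exactly_65_consecutive_successes(self):
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=1000)
        result = smc_decide(lambda: 1, spec)
        assert result.verdict == "accept_h0"
        assert (result.n, result.x) == (65, 65)
        assert result.final_bayes_factor > 1000

    def test_rejects_after_exactly_3_consecutive_failures(self):
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=1000)
        result = smc_decide(lambda: 0, spec)
        assert result.verdict == "reject_h0"
        assert (result.n, result.x) == (3, 0)
        assert result.final_bayes_factor < 1e-3

    def test_undecided_at_sample_cap(self):
        spec = HypothesisTestSpec(theta=0.5, bayes_threshold=1000, max_samples=20)
        outcomes = iter([1, 0] * 10)
        result = smc_decide(lambda: next(outcomes), spec)
        assert result.verdict == "undecided"
        assert result.n == 20

    def test_sampler_failure_reports_index(self):
        spec = HypothesisTestSpec()

        def bad():
            raise OSError("boom")

        with pytest.raises(RuntimeError, match="sample 1"):
            smc_decide(bad, spec)

    def test_error_bound_is_reciprocal_threshold(self):
        assert error_bound(HypothesisTestSpec(bayes_threshold=1000)) == 1e-3
        assert error_bound(HypothesisTestSpec(bayes_threshold=2)) == 0.5
        assert error_bound(HypothesisTestSpec(bayes_threshold=1e6)) == 1e-6

    def test_empirical_error_control_quick(self):
        # small version of the error-control study (the full one runs in the
        # acceptance suite): wrong verdicts stay within the 1/T bound
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=1000)
        wrong = 0
        runs = 400
        for i in range(runs):
            r0 = smc_decide(make_bernoulli_sampler(0.95, seed=i), spec)
            wrong += r0.verdict == "reject_h0"
            r1 = smc_decide(make_bernoulli_sampler(0.80, seed=10_000 + i), spec)
            wrong += r1.verdict == "accept_h0"
        rate = wrong / (2 * runs)
        se = np.sqrt(1e-3 * (1 - 1e-3) / (2 * runs))
        assert rate <= 1e-3 + 3 * se

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            HypothesisTestSpec(theta=1.5)
        with pytest.raises(ValueError):
            HypothesisTestSpec(bayes_threshold=0.5)
        with pytest.raises(ValueError):
            HypothesisTestSpec(p_h0=0.4, p_h1=0.7)


class TestVerifyProperty:
    def test_tautology_accepted_quickly(self):
        net = make_toy_network("birth_death", k=5, d=0.1)
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=10)
        result = verify_property(net, "G^5(A >= 0)", spec, base_seed=42)
        assert result.verdict == "accept_h0"

    def test_impossible_property_rejected(self):
        net = make_toy_network("decay", d=1e-9, A0=10)
        spec = HypothesisTestSpec(theta=0.9, bayes_threshold=10)
        result = verify_property(net, "F^5(A > 100)", spec, base_seed=42)
        assert result.verdict == "reject_h0"

    def test_replay_reproduces_identical_result(self):
        net = make_toy_network("birth_death", k=10, d=0.05)
        spec = HypothesisTestSpec(theta=0.5, bayes_threshold=100, max_samples=200)
        a = verify_property(net, "F^30(A > 150)", spec, base_seed=7)
        b = verify_property(net, "F^30(A > 150)", spec, base_seed=7)
        assert (a.verdict, a.n, a.x) == (b.verdict, b.n, b.x)
        assert a.sample_log == b.sample_log
        # per-sample seeds recorded for replay
        assert [s for s, _ in a.sample_log] == [7 + i for i in range(a.n)]


try:
    from hypothesis import given, settings, strategies as st

    class TestBayesFactorProperties:
        @settings(deadline=None, max_examples=200, derandomize=True)
        @given(n=st.integers(0, 60), theta=st.floats(0.05, 0.95),
               alpha=st.floats(0.2, 5.0), beta=st.floats(0.2, 5.0))
        def test_more_successes_never_lower_evidence(self, n, theta, alpha, beta):
            spec = HypothesisTestSpec(theta=theta, bayes_threshold=1000,
                                      alpha=alpha, beta=beta)
            values = [bayes_factor(x, n, spec) for x in range(n + 1)]
            assert all(b >= a * (1 - 1e-12) for a, b in zip(values, values[1:]))
except ImportError:  # pragma: no cover
    pass
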