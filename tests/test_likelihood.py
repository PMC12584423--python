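import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from behavar import (
    ModelSpec,
    Parameters,
    PriorConfig,
    build_design,
    log_likelihood_pointwise,
    log_prior,
    simulate_responses,
)
from behavar.likelihood import marginal_loglik

from helpers import make_design, make_table


class TestPointwiseLoglik:
    def test_at_mean_unit_sigma_closed_form(self):
        design = make_design([2.0], X=np.array([[2.0]]))
        params = Parameters(beta=[1.0], a=[], sigma_a=[1.0], sigma_w=[1.0])
        ll = log_likelihood_pointwise(params, design)
        np.testing.assert_allclose(ll, [-0.9189385332046727], rtol=1e-12)

    def test_doubling_sigma_at_mean_costs_log2(self):
        design = make_design([0.0])
        p1 = Parameters(beta=[0.0], a=[], sigma_a=[1.0], sigma_w=[1.0])
        p2 = Parameters(beta=[0.0], a=[], sigma_a=[1.0], sigma_w=[2.0])
        d = log_likelihood_pointwise(p1, design) - log_likelihood_pointwise(p2, design)
        np.testing.assert_allclose(d, [np.log(2.0)], rtol=1e-12)

    def test_matches_scipy_density_oracle(self, rng):
        y = rng.normal(size=10)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        groups = rng.integers(0, 4, size=10)
        design = make_design(y, X=X, group_of_obs=groups, n_individuals=4,
                             individual_index=rng.integers(0, 4, size=10))
        params = Parameters(beta=[0.3, -0.7], a=rng.normal(size=4),
                            sigma_a=[1.0], sigma_w=[0.5, 1.0, 1.5, 2.0])
        mu = X @ params.beta + params.a[design.individual_index]
        sd = params.sigma_w[groups]
        expected = stats.norm.logpdf(y, mu, sd)
        np.testing.assert_allclose(
            log_likelihood_pointwise(params, design), expected, rtol=1e-12
        )

    def test_nonpositive_sigma_raises(self):
        design = make_design([0.0])
        params = Parameters(beta=[0.0], a=[], sigma_a=[1.0], sigma_w=[0.0])
        with pytest.raises(ValueError):
            log_likelihood_pointwise(params, design)

    def test_nesting_m4_equals_m1_at_matched_parameters(self):
        table = make_table(group_sizes=(2, 2, 2, 2), seed=3)
        m1, m4 = ModelSpec.from_id("M1"), ModelSpec.from_id("M4")
        d1 = build_design(table, m1)
        d4 = build_design(table, m4)
        a = np.random.default_rng(0).normal(size=d1.n_individuals)
        beta = np.random.default_rng(1).normal(size=d1.n_coef)
        p1 = Parameters(beta=beta, a=a, sigma_a=[0.8], sigma_w=[1.3])
        p4 = Parameters(beta=beta, a=a, sigma_a=[0.8] * 4, sigma_w=[1.3] * 4)
        np.testing.assert_allclose(
            log_likelihood_pointwise(p4, d4), log_likelihood_pointwise(p1, d1),
            atol=1e-12,
        )


class TestLogPrior:
    def _toy(self):
        design = make_design(np.zeros(4), n_individuals=2)
        params = Parameters(beta=[0.4], a=[0.1, -0.2], sigma_a=[0.9], sigma_w=[1.1])
        return design, params

    def test_term_by_term_oracle(self):
        design, params = self._toy()
        prior = PriorConfig(beta_scale=5.0, sd_df=3.0, sd_scale=2.5)
        spec = ModelSpec.from_id("M1")
        expected = (
            stats.norm.logpdf(0.4, scale=5.0)
            + np.log(2) + stats.t.logpdf(0.9 / 2.5, 3) - np.log(2.5)
            + np.log(2) + stats.t.logpdf(1.1 / 2.5, 3) - np.log(2.5)
            + stats.norm.logpdf(0.1, scale=0.9)
            + stats.norm.logpdf(-0.2, scale=0.9)
        )
        np.testing.assert_allclose(
            log_prior(params, prior, spec, design), expected, rtol=1e-12
        )

    def test_negative_sigma_gives_minus_infinity(self):
        design, params = self._toy()
        params.sigma_a = np.array([-1.0])
        assert log_prior(params, PriorConfig(), ModelSpec.from_id("M1"), design) == -np.inf

    def test_wider_beta_scale_favours_large_coefficients(self):
        design, params = self._toy()
        params.beta = np.array([8.0])
        spec = ModelSpec.from_id("M1")
        lp_narrow = log_prior(params, PriorConfig(beta_scale=5.0), spec, design)
        lp_wide = log_prior(params, PriorConfig(beta_scale=10.0), spec, design)
        assert lp_wide > lp_narrow

    def test_group_specific_sigma_a_uses_individual_groups(self):
        y = np.zeros(4)
        design = make_design(y, group_of_obs=[0, 0, 1, 1], n_individuals=2,
                             individual_index=[0, 0, 1, 1])
        params = Parameters(beta=[0.0], a=[0.5, 0.5], sigma_a=[1.0, 2.0, 1.0, 1.0],
                            sigma_w=[1.0])
        spec = ModelSpec.from_id("M2")
        lp = log_prior(params, PriorConfig(), spec, design)
        # intercept of individual 1 is judged under sigma_a=2, not 1
        base = log_prior(
            Parameters(beta=[0.0], a=[0.5, 0.5], sigma_a=[1.0, 1.0, 1.0, 1.0],
                       sigma_w=[1.0]),
            PriorConfig(), spec, design,
        )
        delta = stats.norm.logpdf(0.5, scale=2.0) - stats.norm.logpdf(0.5, scale=1.0)
        prior_delta = (
            np.log(2) + stats.t.logpdf(2.0 / 2.5, 3) - np.log(2.5)
            - (np.log(2) + stats.t.logpdf(1.0 / 2.5, 3) - np.log(2.5))
        )
        np.testing.assert_allclose(lp - base, delta + prior_delta, rtol=1e-10)


class TestSimulate:
    def test_noiseless_limit_returns_linear_predictor(self, rng):
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        design = make_design(np.zeros(6), X=X)
        params = Parameters(beta=[1.5, -2.0], a=[], sigma_a=[0.0], sigma_w=[0.0])
        y = simulate_responses(params, design, seed=1)
        np.testing.assert_array_equal(y, X @ params.beta)

    def test_residual_sd_recovered_at_scale(self):
        n = 10_000
        design = make_design(np.zeros(n))
        params = Parameters(beta=[0.0], a=[], sigma_a=[1.0], sigma_w=[2.0])
        y = simulate_responses(params, design, seed=123)
        assert 1.94 <= y.std(ddof=1) <= 2.06  # chi-square bounds at n=10k

    def test_same_seed_identical(self):
        design = make_design(np.zeros(50))
        params = Parameters(beta=[0.3], a=[], sigma_a=[1.0], sigma_w=[1.0])
        np.testing.assert_array_equal(
            simulate_responses(params, design, seed=9),
            simulate_responses(params, design, seed=9),
        )


def test_conditional_vs_analytic_marginal_likelihood(rng):
    """Monte-Carlo marginalization over a_i agrees with the closed-form
    Gaussian integral on a 5-observation instance."""
    y = rng.normal(size=5)
    design = make_design(y, n_individuals=2, individual_index=[0, 0, 0, 1, 1])
    beta = np.array([0.2])
    sigma_a, sigma_w = 0.7, 1.2
    exact = marginal_loglik(
        Parameters(beta=beta, a=[0.0, 0.0], sigma_a=[sigma_a], sigma_w=[sigma_w]), design
    )
    draws = 200_000
    a = rng.normal(0.0, sigma_a, size=(draws, 2))
    mu = design.X @ beta
    ll = np.zeros(draws)
    for i, idx in enumerate(([0, 1, 2], [3, 4])):
        r = y[idx][None, :] - mu[idx][None, :] - a[:, [i]]
        ll += np.sum(stats.norm.logpdf(r, scale=sigma_w), axis=1)
    mc = logsumexp(ll) - np.log(draws)
    assert abs(mc - exact) < 0.02
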