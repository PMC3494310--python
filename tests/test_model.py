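"""Distribution primitives, the joint posterior, the sampler contract and
convergence diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from reefsharks import model
from reefsharks.model import (
    ModelData,
    ModelSpec,
    ParameterState,
    PriorSpec,
    gelman_rubin,
    linear_predictor,
    log_posterior,
    nb_log_pmf,
    run_mcmc,
    tow_mean,
    truncnorm_log_pdf,
)


class TestNegativeBinomial:
    def test_zero_mean_makes_zero_certain(self):
        assert nb_log_pmf(0, 0.0, 1.0) == 0.0
        assert nb_log_pmf(2, 0.0, 1.0) == -np.inf

    def test_geometric_closed_form_at_k_one(self):
        # k=1 reduces to geometric with success prob 1/(1+lam)
        p = 1.0 / 3.0
        assert nb_log_pmf(3, 2.0, 1.0) == pytest.approx(math.log(p * (1 - p) ** 3),
                                                        abs=1e-12)
        assert nb_log_pmf(3, 2.0, 1.0) == pytest.approx(math.log(8 / 81), abs=1e-12)

    def test_poisson_limit_at_large_k(self):
        assert nb_log_pmf(4, 3.0, 1e6) == pytest.approx(
            stats.poisson.logpmf(4, 3.0), abs=1e-4
        )

    @pytest.mark.parametrize("k", [0.5, 1.0, 5.0])
    @pytest.mark.parametrize("lam", [0.3, 2.0, 20.0])
    def test_normalizes(self, lam, k):
        y = np.arange(0, 4000)
        total = np.exp(nb_log_pmf(y, lam, k)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1, -0.5, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 1.0, 0.0)

    def test_matches_scipy_parameterization(self):
        # mean lam, variance lam + lam^2/k  <=>  scipy nbinom(n=k, p=k/(k+lam))
        y, lam, k = 7, 3.5, 2.3
        assert nb_log_pmf(y, lam, k) == pytest.approx(
            stats.nbinom.logpmf(y, k, k / (k + lam)), abs=1e-12
        )


class TestTowMean:
    def test_density_times_area(self):
        assert tow_mean(0.0, 2.2) == 0.0
        assert tow_mean(2.0, 2.2) == pytest.approx(4.4)
        assert tow_mean(1.3, 4.0) == pytest.approx(2 * tow_mean(1.3, 2.0))


class TestTruncatedNormal:
    def test_half_normal_closed_form(self):
        assert truncnorm_log_pdf(0.5, 0.0, 1.0) == pytest.approx(
            math.log(2 * stats.norm.pdf(0.5)), abs=1e-12
        )

    def test_negligible_truncation_matches_normal(self):
        assert truncnorm_log_pdf(10.0, 10.0, 1.0) == pytest.approx(
            stats.norm.logpdf(10.0, 10.0, 1.0), abs=1e-10
        )

    def test_nonpositive_support(self):
        assert truncnorm_log_pdf(-0.1, 0.0, 1.0) == -np.inf
        assert truncnorm_log_pdf(0.0, 0.0, 1.0) == -np.inf

    @pytest.mark.parametrize("E,var", [(0.0, 1.0), (2.0, 0.25), (-1.5, 4.0)])
    def test_normalizes_by_quadrature(self, E, var):
        total, _ = integrate.quad(
            lambda m: math.exp(truncnorm_log_pdf(m, E, var)), 0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            truncnorm_log_pdf(1.0, 0.0, -1.0)


class TestLinearPredictor:
    def test_indicators_gate_effects(self):
        assert linear_predictor(2.5, [1.0, -3.0], [0, 0], [[5.0, 5.0]]) == 2.5

    def test_forced_arithmetic(self):
        assert linear_predictor(1.0, [2.0, -1.0], [1, 1], [[0.5, 1.0]]) == pytest.approx(
            1.0
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.permutations(range(4)))
    def test_permutation_invariant(self, perm):
        beta = np.array([0.5, -1.0, 2.0, 0.0])
        w = np.array([1, 0, 1, 1])
        x = np.array([[0.3, -0.7, 1.1, 2.0]])
        base = linear_predictor(0.2, beta, w, x)
        p = list(perm)
        assert linear_predictor(0.2, beta[p], w[p], x[:, p]) == pytest.approx(base)


def toy_data(two_islands=True):
    if two_islands:
        return ModelData(
            y=np.array([1, 0, 3], dtype=np.int64),
            area=np.array([2.0, 1.5, 2.2]),
            isl_start=np.array([0, 2, 3], dtype=np.int64),
            island_ids=["A", "B"],
            n_per_island=np.array([2.0, 1.0]),
            X=np.array([[0.5], [-0.5]]),
            columns=["hum"],
        )
    return ModelData(
        y=np.array([1, 0], dtype=np.int64),
        area=np.array([2.0, 1.5]),
        isl_start=np.array([0, 2], dtype=np.int64),
        island_ids=["A"],
        n_per_island=np.array([2.0]),
        X=np.array([[0.5]]),
        columns=["hum"],
    )


class TestLogPosterior:
    STATE = ParameterState(
        alpha=0.5, beta=np.array([0.4]), sigma2=0.8, k=1.2,
        mu=np.array([0.6, 1.1]), w=np.array([1]),
    )

    def test_term_by_term_composition(self):
        """The joint equals the hand-summed NB + truncated-normal + prior terms."""
        data = toy_data()
        spec = ModelSpec(covariates=("hum",), selection=True)
        s = self.STATE
        expect = 0.0
        lam = [s.mu[0] * 2.0, s.mu[0] * 1.5, s.mu[1] * 2.2]
        for y, lm in zip([1, 0, 3], lam):
            expect += nb_log_pmf(y, lm, s.k)
        for i, n_i in enumerate([2.0, 1.0]):
            E_i = s.alpha + s.w[0] * s.beta[0] * data.X[i, 0]
            expect += truncnorm_log_pdf(s.mu[i], E_i, s.sigma2 / n_i)
        expect += stats.norm.logpdf(s.alpha, 0, 10)
        expect += stats.norm.logpdf(s.beta[0], 0, 10)
        a = b = 0.01
        expect += a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(s.sigma2) \
            - b / s.sigma2
        expect += stats.gamma.logpdf(s.k, 0.01, scale=1 / 0.01)
        expect += math.log(0.5)
        assert log_posterior(s, data, spec) == pytest.approx(expect, abs=1e-10)

    def test_additive_in_islands(self):
        """Dropping one island's tows and its mu removes exactly its terms."""
        data = toy_data()
        sub = toy_data(two_islands=False)
        spec = ModelSpec(covariates=("hum",))
        s = self.STATE
        s1 = ParameterState(alpha=0.5, beta=np.array([0.4]), sigma2=0.8, k=1.2,
                            mu=np.array([0.6]), w=np.array([1]))
        delta = log_posterior(s, data, spec) - log_posterior(s1, sub, spec)
        E_b = s.alpha + s.beta[0] * data.X[1, 0]
        expect = nb_log_pmf(3, s.mu[1] * 2.2, s.k) + truncnorm_log_pdf(
            s.mu[1], E_b, s.sigma2 / 1.0
        )
        assert delta == pytest.approx(expect, abs=1e-10)

    def test_island_reordering_invariance(self):
        data = toy_data()
        flipped = ModelData(
            y=np.array([3, 1, 0], dtype=np.int64),
            area=np.array([2.2, 2.0, 1.5]),
            isl_start=np.array([0, 1, 3], dtype=np.int64),
            island_ids=["B", "A"],
            n_per_island=np.array([1.0, 2.0]),
            X=np.array([[-0.5], [0.5]]),
            columns=["hum"],
        )
        spec = ModelSpec(covariates=("hum",))
        s = self.STATE
        s_flip = ParameterState(alpha=0.5, beta=np.array([0.4]), sigma2=0.8,
                                k=1.2, mu=np.array([1.1, 0.6]), w=np.array([1]))
        assert log_posterior(s, data, spec) == pytest.approx(
            log_posterior(s_flip, flipped, spec), abs=1e-12
        )

    def test_decreasing_in_island_deviation(self):
        data = toy_data()
        spec = ModelSpec(covariates=("hum",))
        base = log_posterior(self.STATE, data, spec)
        far = ParameterState(alpha=0.5, beta=np.array([0.4]), sigma2=0.8, k=1.2,
                             mu=np.array([3.0, 3.5]), w=np.array([1]))
        assert log_posterior(far, data, spec) < base

    def test_nonpositive_mu_is_impossible(self):
        data = toy_data()
        spec = ModelSpec(covariates=("hum",))
        s = ParameterState(alpha=0.5, beta=np.array([0.4]), sigma2=0.8, k=1.2,
                           mu=np.array([0.6, -0.1]), w=np.array([1]))
        assert log_posterior(s, data, spec) == -np.inf


class TestSampler:
    def test_same_seed_bit_identical(self, sim_fit):
        data, spec = sim_fit["data"], sim_fit["fit"].spec
        a = run_mcmc(data, spec, n_iter=800, n_burn=200, seed=42)
        b = run_mcmc(data, spec, n_iter=800, n_burn=200, seed=42)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.k, b.k)

    def test_flat_data_concentrates_at_moment_estimate(self):
        """Constant counts on one island: mu posterior sits at count/area."""
        n = 150
        data = ModelData(
            y=np.full(n, 4, dtype=np.int64),
            area=np.full(n, 2.0),
            isl_start=np.array([0, n], dtype=np.int64),
            island_ids=["A"],
            n_per_island=np.array([float(n)]),
            X=np.zeros((1, 0)),
            columns=[],
        )
        fit = run_mcmc(data, ModelSpec(covariates=()), n_iter=4000, n_burn=1000,
                       seed=9)
        post_mu = float(np.mean(fit.stacked("mu:A")))
        assert post_mu == pytest.approx(2.0, rel=0.05)

    def test_degenerate_all_zero_warns_not_fails(self):
        n = 20
        data = ModelData(
            y=np.zeros(n, dtype=np.int64),
            area=np.full(n, 2.0),
            isl_start=np.array([0, n], dtype=np.int64),
            island_ids=["A"],
            n_per_island=np.array([float(n)]),
            X=np.zeros((1, 0)),
            columns=[],
        )
        with pytest.warns(RuntimeWarning):
            fit = run_mcmc(data, ModelSpec(covariates=()), n_iter=500, n_burn=100,
                           seed=1)
        assert np.all(fit.stacked("mu") > 0)

    def test_retained_draw_count_and_positivity(self, sim_fit):
        fit = sim_fit["fit"]
        assert fit.n_retained == fit.chains * (fit.n_iter - fit.n_burn)
        assert np.all(fit.stacked("mu") > 0)
        assert np.all(fit.stacked("sigma2") > 0)
        assert np.all(fit.stacked("k") > 0)

    def test_save_load_round_trip(self, sim_fit, tmp_path):
        fit = sim_fit["fit"]
        fit.save(tmp_path / "posterior")
        back = model.PosteriorSamples.load(tmp_path / "posterior", fit.data)
        assert np.array_equal(back.alpha, fit.alpha)
        assert np.array_equal(back.beta, fit.beta)
        assert np.array_equal(back.w, fit.w)
        assert back.spec.link == fit.spec.link


class TestGelmanRubin:
    def test_hand_sized_formula(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        m, n = chains.shape
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B = n * np.var(chains.mean(axis=1), ddof=1)
        expect = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(chains) == pytest.approx(expect, abs=1e-12)

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 20000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_divergent_chains_large(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 3.0

    def test_zero_within_variance_degenerate(self):
        with pytest.warns(RuntimeWarning):
            out = gelman_rubin(np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]))
        assert math.isnan(out)

    def test_on_fitted_samples(self, sim_fit):
        assert gelman_rubin(sim_fit["fit"], "alpha") < 1.1


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(coef_var=-1.0)
    with pytest.raises(ValueError):
        PriorSpec(indicator_prob=1.0)
    with pytest.raises(ValueError):
        ModelSpec(link="probit")
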