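"""Counterfactual baselines, observed densities, depletion arithmetic and
effect summaries."""

import numpy as np
import pytest
from scipy import stats

from reefsharks.baseline import (
    BaselineEstimate,
    baseline_density,
    depletion_ratio,
    doubling_increment,
    effect_curve,
    fitted_density,
    observed_density,
)
from reefsharks.model import ModelData, ModelSpec, PosteriorSamples, truncnorm_mean
from .conftest import make_tow


def fixed_draw_samples(data, alpha, beta, sigma2, k=1.0, link="identity",
                       n_draws=4, selection=False, w=None):
    """Posterior made of identical draws: predictions become closed-form."""
    p = len(data.columns)
    I = data.n_islands
    beta = np.asarray(beta, dtype=float).reshape(p)
    w = np.ones(p, dtype=np.int8) if w is None else np.asarray(w, dtype=np.int8)
    return PosteriorSamples(
        spec=ModelSpec(covariates=tuple(data.columns), link=link,
                       selection=selection),
        data=data, chains=2, n_iter=n_draws, n_burn=0, rng_seed=0,
        alpha=np.full((2, n_draws), alpha),
        beta=np.tile(beta, (2, n_draws, 1)),
        mu=np.ones((2, n_draws, I)),
        sigma2=np.full((2, n_draws), sigma2),
        k=np.full((2, n_draws), k),
        w=np.tile(w, (2, n_draws, 1)),
    )


def two_island_setup():
    from reefsharks.covariates import transform_covariates
    from .conftest import make_islands

    islands = make_islands()
    design = transform_covariates(islands, columns=["humans_200km", "min_sst"])
    data = ModelData(
        y=np.array([2, 1, 0, 5], dtype=np.int64),
        area=np.array([2.0, 2.0, 1.5, 2.5]),
        isl_start=np.array([0, 2, 4], dtype=np.int64),
        island_ids=[islands[0].island_id, islands[3].island_id],
        n_per_island=np.array([2.0, 2.0]),
        X=design.X[[0, 3]][:, :2],
        columns=["humans_200km", "min_sst"],
    )
    return islands, design, data


class TestObservedDensity:
    def test_ratio_of_totals(self):
        frame_like = [
            make_tow("a", length_km=2.0, counts={"GR": 3}),
            make_tow("b", length_km=2.0, counts={"GR": 1}),
        ]
        dens, se = observed_density(frame_like)
        assert dens == pytest.approx(1.0)  # 4 sharks over 4 ha
        assert se > 0

    def test_all_zero_counts(self):
        dens, se = observed_density([make_tow("a"), make_tow("b")])
        assert dens == 0.0 and se == 0.0

    def test_invariant_to_splitting_a_tow(self):
        whole = [make_tow("a", length_km=2.0, counts={"GR": 4})]
        halves = [
            make_tow("a1", length_km=1.0, counts={"GR": 2}),
            make_tow("a2", length_km=1.0, counts={"GR": 2}),
        ]
        assert observed_density(whole)[0] == pytest.approx(
            observed_density(halves)[0]
        )

    def test_zero_tows_error(self):
        with pytest.raises(ValueError):
            observed_density([])


class TestDepletion:
    def test_observed_equals_baseline(self):
        est = BaselineEstimate("A", 2.0, (1.0, 3.0))
        lo, mid, hi = depletion_ratio(2.0, est)
        assert mid == pytest.approx(100.0)

    def test_paper_style_interval_construction(self):
        """observed 0.1/ha over baseline CI (1.2, 2.4) gives ~4-8%."""
        est = BaselineEstimate("AmSamoa", 1.7, (1.2, 2.4))
        lo, mid, hi = depletion_ratio(0.1, est)
        assert lo == pytest.approx(100 * 0.1 / 2.4)
        assert hi == pytest.approx(100 * 0.1 / 1.2)
        assert round(lo, 1) == 4.2 and round(hi, 1) == 8.3

    def test_output_sorted_even_if_bounds_swapped(self):
        est = BaselineEstimate("A", 2.0, (3.0, 1.0))  # malformed order
        lo, mid, hi = depletion_ratio(1.0, est)
        assert lo <= mid <= hi


class TestBaselineDensity:
    def test_zero_human_effect_baseline_equals_fitted(self):
        islands, design, data = two_island_setup()
        samples = fixed_draw_samples(data, alpha=1.5, beta=[0.0, 0.4],
                                     sigma2=0.5)
        for iid in data.island_ids:
            est = baseline_density(samples, design, iid)
            fit = fitted_density(samples, design, iid)
            assert est.baseline_median == pytest.approx(float(np.median(fit)))

    def test_uninhabited_island_counterfactual_is_factual(self):
        islands, design, data = two_island_setup()
        samples = fixed_draw_samples(data, alpha=1.5, beta=[-0.8, 0.4],
                                     sigma2=0.5)
        zero_human = data.island_ids[0]  # I00 has 0 raw humans
        assert islands[0].humans_200km == 0.0
        est = baseline_density(samples, design, zero_human)
        fit = fitted_density(samples, design, zero_human)
        assert est.baseline_median == pytest.approx(float(np.median(fit)),
                                                    rel=1e-12)

    def test_single_draw_matches_truncnorm_moment_formula(self):
        islands, design, data = two_island_setup()
        alpha, beta, sigma2 = 0.8, [-0.6, 0.3], 0.9
        samples = fixed_draw_samples(data, alpha, beta, sigma2)
        iid = data.island_ids[1]
        i = design.island_ids.index(iid)
        x = design.X[i, :2].copy()
        x[0] = design.standardize_raw("humans_200km", 0.0)
        E = alpha + float(np.dot(beta, x))
        s = np.sqrt(sigma2 / 2.0)
        expect = E + s * stats.norm.pdf(E / s) / stats.norm.cdf(E / s)
        est = baseline_density(samples, design, iid)
        assert est.baseline_median == pytest.approx(expect, rel=1e-10)
        assert est.baseline_ci[0] == pytest.approx(est.baseline_ci[1])

    def test_unknown_island_raises(self):
        _, design, data = two_island_setup()
        samples = fixed_draw_samples(data, 1.0, [0.0, 0.0], 0.5)
        with pytest.raises(KeyError):
            baseline_density(samples, design, "Atlantis")


class TestEffectCurve:
    def test_flat_when_coefficient_zero(self):
        _, design, data = two_island_setup()
        samples = fixed_draw_samples(data, 1.2, [0.0, 0.0], 0.5)
        curve = effect_curve(samples, design, "min_sst", n_grid=7)
        assert np.allclose(curve.median, curve.median[0])
        assert np.all(curve.lo <= curve.median) and np.all(
            curve.median <= curve.hi
        )

    def test_grid_strictly_increasing(self):
        _, design, data = two_island_setup()
        samples = fixed_draw_samples(data, 1.2, [0.3, -0.2], 0.5)
        curve = effect_curve(samples, design, "min_sst", n_grid=9)
        assert np.all(np.diff(curve.x_raw) > 0)

    def test_log_link_power_function_in_logged_covariate(self):
        """Under the log link, exp(alpha + beta log x) = C x^beta: the curve
        over a log-transformed covariate follows a power law."""
        _, design, data = two_island_setup()
        beta_h = -0.7
        samples = fixed_draw_samples(
            data, 0.2, [beta_h, 0.0], sigma2=1e-8, link="log"
        )
        curve = effect_curve(samples, design, "humans_200km", n_grid=12)
        m = design.transform_meta["humans_200km"]
        x_t = np.log(curve.x_raw + m["offset"])  # transformed scale
        # density ~ C * exp(beta_std * (x_t - mean)/sd): log-linear in x_t
        slope = np.polyfit(x_t, np.log(curve.median), 1)[0]
        assert slope == pytest.approx(beta_h / m["sd"], rel=1e-6)

    def test_monotone_when_posterior_sign_fixed(self):
        _, design, data = two_island_setup()
        samples = fixed_draw_samples(data, 1.5, [0.0, 0.6], sigma2=0.3)
        curve = effect_curve(samples, design, "min_sst", n_grid=15)
        assert np.all(np.diff(curve.median) > 0)


class TestDoublingIncrement:
    def test_definition(self):
        _, design, data = two_island_setup()
        sd = design.transform_meta["min_sst"]["sd"]
        samples = fixed_draw_samples(data, 0.5, [0.0, np.log(2.0)],
                                     sigma2=1e-8, link="log")
        inc = doubling_increment(samples, design, "min_sst")
        assert inc == pytest.approx(sd, rel=1e-12)

    def test_scales_with_raw_spread(self):
        _, design, data = two_island_setup()
        samples = fixed_draw_samples(data, 0.5, [0.0, 0.4], sigma2=1e-8,
                                     link="log")
        inc = doubling_increment(samples, design, "min_sst")
        design.transform_meta["min_sst"]["sd"] *= 2.0
        assert doubling_increment(samples, design, "min_sst") == pytest.approx(
            2 * inc
        )
        design.transform_meta["min_sst"]["sd"] /= 2.0

    def test_density_doubles_over_increment_under_log_link(self):
        _, design, data = two_island_setup()
        beta = 0.8
        samples = fixed_draw_samples(data, 0.3, [0.0, beta], sigma2=1e-10,
                                     link="log")
        inc = doubling_increment(samples, design, "min_sst")
        m = design.transform_meta["min_sst"]
        x0 = 24.0
        z0 = design.standardize_raw("min_sst", x0)
        z1 = design.standardize_raw("min_sst", x0 + inc)
        d0 = truncnorm_mean(np.exp(0.3 + beta * z0), 1e-5)
        d1 = truncnorm_mean(np.exp(0.3 + beta * z1), 1e-5)
        assert d1 / d0 == pytest.approx(2.0, abs=1e-9)

    def test_no_doubling_for_negative_effect(self):
        _, design, data = two_island_setup()
        samples = fixed_draw_samples(data, 0.5, [-0.4, 0.0], sigma2=1e-8,
                                     link="log")
        assert doubling_increment(samples, design, "humans_200km") is None
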