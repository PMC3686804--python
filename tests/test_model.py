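"""Effort function, linear predictor assembly and the joint log density,
each checked against an independently coded oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cbctrend as ct
from cbctrend.data import SurveyDataset
from cbctrend.errors import UnidentifiableModelError
from cbctrend.model import CircleCountModel, Hyperpriors, ModelParams


class TestEffortEffect:
    def test_zero_at_mean_effort(self):
        for B, p in [(0.3, 0.5), (-1.2, 2.0), (5.0, 0.01)]:
            assert ct.effort_effect(12.0, B, p, 12.0) == pytest.approx(0.0)

    def test_linear_case(self):
        assert ct.effort_effect(24.0, 1.0, 1.0, 12.0) == pytest.approx(1.0)

    def test_small_p_limit_matches_log_oracle(self):
        # p -> 0: f -> B log(zeta/zeta_m); series oracle at p = 1e-8
        got = ct.effort_effect(24.0, 1.0, 1e-8, 12.0)
        assert abs(got - math.log(2.0)) <= 1e-6

    def test_continuous_across_small_p_threshold(self):
        lo = ct.effort_effect(30.0, 0.7, 9.9e-5, 10.0)
        hi = ct.effort_effect(30.0, 0.7, 1.01e-4, 10.0)
        assert abs(lo - hi) < 1e-6

    @pytest.mark.parametrize("zeta,zeta_m,p", [(-1, 10, 1), (0, 10, 1),
                                               (10, 0, 1), (10, 10, 0)])
    def test_domain_errors(self, zeta, zeta_m, p):
        with pytest.raises(ValueError):
            ct.effort_effect(zeta, 1.0, p, zeta_m)


def _small_model(seed=0, n_circles=4, n_years=6, missing=0.15,
                 effort_sd=0.5):
    cfg = ct.recovery_config(-3.0, n_circles=n_circles, mean_count=20.0,
                             seed=seed)
    cfg.n_years = n_years
    cfg.missing_probability = missing
    cfg.effort_log_sd = effort_sd
    return CircleCountModel(ct.simulate_dataset(cfg)[0])


def _random_params(model, rng):
    R, I, T, n = (model.n_regions, model.n_circles, model.n_years,
                  model.n_obs)
    return ModelParams(
        beta0=rng.normal(2.0, 0.5, R), beta1=rng.normal(0, 0.05, R),
        beta2=rng.normal(0, 0.1),
        circle_effects=rng.normal(0, 0.5, I),
        year_effects=rng.normal(0, 0.2, T),
        noise=rng.normal(0, 0.3, n),
        effort_B=rng.normal(0, 0.5), effort_p=rng.uniform(0.1, 2.0),
        var_circle=0.5, var_year=0.04, var_noise=0.09,
        hyper_mean_beta0=1.0, hyper_var_beta0=2.0,
        hyper_mean_beta1=0.0, hyper_var_beta1=0.01)


class TestLogExpectedCount:
    def test_identity_at_reference_conditions(self):
        model = _small_model()
        rng = np.random.default_rng(0)
        params = _random_params(model, rng)
        params.beta1[:] = 0
        params.beta2 = 0
        params.circle_effects[:] = 0
        params.year_effects[:] = 0
        params.noise[:] = 0
        params.effort_B = 0
        logmu = model.log_mu(params)
        assert np.allclose(logmu, params.beta0[model.region_idx])

    def test_arithmetic_example(self):
        # 7 years -> integer centred times; pick the row with tau = +2
        model = _small_model(n_years=7, missing=0.0)
        rng = np.random.default_rng(1)
        params = _random_params(model, rng)
        params.beta0[:] = 1.0
        params.beta1[:] = 0.1
        params.beta2 = 0
        params.circle_effects[:] = 0
        params.year_effects[:] = 0
        params.noise[:] = 0
        params.effort_B = 0
        row = int(np.argmax(model.tau == 2.0))
        assert model.tau[row] == 2.0
        assert model.log_expected_count(params, row) == pytest.approx(1.2)

    def test_matches_bruteforce_assembly(self):
        model = _small_model(seed=3)
        rng = np.random.default_rng(7)
        params = _random_params(model, rng)
        logmu = model.log_mu(params)
        for row in range(model.n_obs):
            r = model.region_idx[row]
            expected = (params.beta0[r]
                        + params.beta1[r] * model.tau[row]
                        + params.beta2 * model.boat[row]
                        + params.circle_effects[model.circle_idx[row]]
                        + params.year_effects[model.year_idx[row]]
                        + params.effort_B
                        * ((model.effort[row] / model.zeta_m)
                           ** params.effort_p - 1.0) / params.effort_p
                        + params.noise[row])
            assert abs(logmu[row] - expected) <= 1e-12

    def test_row_out_of_range(self):
        model = _small_model()
        params = _random_params(model, np.random.default_rng(0))
        with pytest.raises(LookupError):
            model.log_expected_count(params, model.n_obs)


def _oracle_log_posterior(model, params, priors):
    """Straight scipy summation of every density term."""
    logmu = model.log_mu(params)
    lp = stats.poisson.logpmf(model.y, np.exp(logmu)).sum()
    lp += stats.norm.logpdf(params.circle_effects, 0,
                            math.sqrt(params.var_circle)).sum()
    lp += stats.norm.logpdf(params.year_effects, 0,
                            math.sqrt(params.var_year)).sum()
    lp += stats.norm.logpdf(params.noise, 0,
                            math.sqrt(params.var_noise)).sum()
    sd_coef = math.sqrt(priors.coef_variance)
    if model.n_regions > 1:
        lp += stats.norm.logpdf(params.beta0, params.hyper_mean_beta0,
                                math.sqrt(params.hyper_var_beta0)).sum()
        lp += stats.norm.logpdf(params.beta1, params.hyper_mean_beta1,
                                math.sqrt(params.hyper_var_beta1)).sum()
        lp += stats.norm.logpdf(params.hyper_mean_beta0, 0, sd_coef)
        lp += stats.norm.logpdf(params.hyper_mean_beta1, 0, sd_coef)
        lp += stats.invgamma.logpdf(params.hyper_var_beta0, priors.ig_shape,
                                    scale=priors.ig_scale)
        lp += stats.invgamma.logpdf(params.hyper_var_beta1, priors.ig_shape,
                                    scale=priors.ig_scale)
    else:
        lp += stats.norm.logpdf(params.beta0, 0, sd_coef).sum()
        lp += stats.norm.logpdf(params.beta1, 0, sd_coef).sum()
    lp += stats.norm.logpdf(params.beta2, 0, sd_coef)
    lp += stats.norm.logpdf(params.effort_B, 0, sd_coef)
    lp += stats.norm.logpdf(math.log(params.effort_p), 0, priors.log_p_sd)
    for v in (params.var_circle, params.var_year, params.var_noise):
        lp += stats.invgamma.logpdf(v, priors.ig_shape, scale=priors.ig_scale)
    return float(lp)


class TestLogPosterior:
    def test_matches_independent_summation(self):
        priors = Hyperpriors()
        for seed in (0, 1, 2):
            model = _small_model(seed=seed)
            params = _random_params(model, np.random.default_rng(seed + 10))
            ours = model.log_posterior(params, priors)
            oracle = _oracle_log_posterior(model, params, priors)
            assert abs(ours - oracle) <= 1e-9

    def test_zero_count_poisson_term(self):
        # with mu = 1 each observed zero contributes exactly log(e^-1) = -1
        records = pd.DataFrame(
            [("A", 2000, "WEST", 0, 8.0, 0), ("A", 2001, "WEST", 0, 8.0, 0),
             ("B", 2000, "WEST", 0, 8.0, 0), ("B", 2001, "WEST", 0, 8.0, 0)],
            columns=["circle_id", "year", "species", "count", "effort_hours",
                     "boat_used"])
        circles = pd.DataFrame(
            [("A", 48.0, -123.0, 5.0, "Salish Sea"),
             ("B", 48.5, -123.1, 5.0, "Salish Sea")],
            columns=["circle_id", "latitude", "longitude", "coast_distance_km",
                     "region"])
        model = CircleCountModel(SurveyDataset(records, circles))
        params = ModelParams(
            beta0=np.zeros(1), beta1=np.zeros(1), beta2=0.0,
            circle_effects=np.zeros(2), year_effects=np.zeros(2),
            noise=np.zeros(4), effort_B=0.0, effort_p=1.0,
            var_circle=1.0, var_year=1.0, var_noise=1.0)
        priors = Hyperpriors()
        prior_only = _oracle_log_posterior(model, params, priors) + 4.0
        assert model.log_posterior(params, priors) == pytest.approx(prior_only - 4.0)
        assert model.log_posterior(params, priors) - prior_only == pytest.approx(-4.0)

    def test_missing_surveys_contribute_nothing(self):
        # constant effort so dropping a survey leaves zeta_m unchanged
        model_full = _small_model(seed=5, effort_sd=0.0)
        ds = model_full.dataset
        # drop the first aggregated circle-year entirely
        key = model_full.obs.iloc[0]
        keep = ~((ds.records.circle_id == key.circle_id)
                 & (ds.records.year == key.year))
        model_miss = CircleCountModel(
            SurveyDataset(ds.records[keep].copy(), ds.circles.copy(),
                          ds.year_range))
        priors = Hyperpriors()
        rng = np.random.default_rng(3)
        params = _random_params(model_full, rng)
        row = 0  # the dropped observation's row in the full model
        params_miss = ModelParams(
            **{**params.__dict__,
               "noise": np.delete(params.noise, row)})
        lp_full = model_full.log_posterior(params, priors)
        lp_miss = model_miss.log_posterior(params_miss, priors)
        mu = math.exp(model_full.log_mu(params)[row])
        removed = (stats.poisson.logpmf(model_full.y[row], mu)
                   + stats.norm.logpdf(params.noise[row], 0,
                                       math.sqrt(params.var_noise)))
        assert lp_full - lp_miss == pytest.approx(removed, abs=1e-9)

    def test_invalid_params_give_minus_inf(self):
        model = _small_model()
        params = _random_params(model, np.random.default_rng(0))
        params.var_noise = -1.0
        assert model.log_posterior(params) == -np.inf

    def test_finite_for_valid_params(self):
        model = _small_model()
        for seed in range(5):
            params = _random_params(model, np.random.default_rng(seed))
            assert np.isfinite(model.log_posterior(params))


class TestModelConstruction:
    def test_single_circle_unidentifiable(self):
        records = pd.DataFrame(
            [("A", 2000 + t, "WEST", 5, 8.0, 0) for t in range(5)],
            columns=["circle_id", "year", "species", "count", "effort_hours",
                     "boat_used"])
        circles = pd.DataFrame(
            [("A", 48.0, -123.0, 5.0, "Salish Sea")],
            columns=["circle_id", "latitude", "longitude", "coast_distance_km",
                     "region"])
        with pytest.raises(UnidentifiableModelError):
            CircleCountModel(SurveyDataset(records, circles))

    def test_single_year_unidentifiable(self):
        records = pd.DataFrame(
            [(c, 2000, "WEST", 5, 8.0, 0) for c in "ABCD"],
            columns=["circle_id", "year", "species", "count", "effort_hours",
                     "boat_used"])
        circles = pd.DataFrame(
            [(c, 48.0, -123.0, 5.0, "Salish Sea") for c in "ABCD"],
            columns=["circle_id", "latitude", "longitude", "coast_distance_km",
                     "region"])
        with pytest.raises(UnidentifiableModelError):
            CircleCountModel(SurveyDataset(records, circles))
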