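"""Sampler tests: convergence diagnostics, determinism, analytic limits,
and the marginalized-vs-latent cross-validation."""

import numpy as np
import pandas as pd
import pytest

import thresholdnmix as t
from thresholdnmix.mcmc import FitData


def flat_fit_data(count=12, n=80, seed=0):
    rng = np.random.default_rng(seed)
    return FitData(
        design=t.ModelDesign("direct", "grass", "3km"),
        y=np.full(n, count, dtype=int),
        weather_x=np.zeros((n, 4)),
        hinge_x=rng.uniform(-1.5, 1.5, size=n),
        cells=pd.DataFrame({"route_id": np.arange(n), "year": 2000, "climate_region": 0}),
    )


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=1000)
        rhat = t.gelman_rubin({"x": np.stack([chain, chain, chain])}, "x")
        assert rhat == pytest.approx(1.0, abs=1e-2)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert t.gelman_rubin({"x": chains}, "x") > 3.0

    def test_well_mixed_chains_below_105(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 5000))
        assert t.gelman_rubin({"x": chains}, "x") < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            t.gelman_rubin({"x": np.zeros((1, 100))}, "x")

    def test_matches_classic_formula(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 200)) + rng.normal(size=(3, 1))
        m, n = chains.shape
        W = chains.var(axis=1, ddof=1).mean()
        B_over_n = chains.mean(axis=1).var(ddof=1)
        expect = np.sqrt(((n - 1) / n * W + (1 + 1 / m) * B_over_n) / W)
        assert t.gelman_rubin({"x": chains}, "x") == pytest.approx(expect, rel=1e-12)


class TestSampler:
    def test_identical_seeds_identical_draws(self):
        data = flat_fit_data(n=40)
        mc = t.McmcConfig(n_chains=2, burn_in=200, n_saved=100, seed=3)
        s1 = t.sample_posterior(data.design, data, config=mc)
        s2 = t.sample_posterior(data.design, data, config=mc)
        for name in s1.parameter_names:
            np.testing.assert_array_equal(s1.draws[name], s2.draws[name])

    def test_flat_data_recovers_log_mean(self):
        # constant counts, no covariate structure: beta0 ~ log(count)
        data = flat_fit_data(count=12, n=80)
        mc = t.McmcConfig(n_chains=2, burn_in=2500, n_saved=1000, seed=4)
        samples = t.sample_posterior(data.design, data, config=mc)
        b0 = samples.pooled("beta0")
        assert abs(np.mean(b0) - np.log(12)) < 2 * np.std(b0)

    def test_phi_draws_stay_in_bounds(self, small_direct_fit):
        data, samples = small_direct_fit
        lo, hi = samples.meta["phi_bounds"]
        phi = samples.pooled("phi")
        assert phi.min() >= lo and phi.max() <= hi

    def test_chain_order_invariance_of_pooled_summaries(self, small_direct_fit):
        _, samples = small_direct_fit
        pooled = samples.pooled("beta0")
        swapped = t.PosteriorSamples(
            draws={"beta0": samples.draws["beta0"][::-1].copy()}, meta=samples.meta
        )
        assert np.mean(swapped.pooled("beta0")) == pytest.approx(np.mean(pooled))

    def test_latent_sampling_rejected_for_direct(self):
        data = flat_fit_data()
        with pytest.raises(ValueError):
            t.sample_posterior(
                data.design, data, config=t.McmcConfig(latent_n="sampled")
            )

    def test_marginalized_and_latent_agree(self):
        # same lek fixture through both samplers: posteriors should agree
        # within Monte-Carlo error
        truth = t.ThresholdModelParams(beta0=1.8, r=4.0, p=0.65, sigma=0.0)
        cfg = t.SimulationConfig(
            n_routes=12, year_start=2000, year_end=2009, n_visits=2,
            contract_periods=((2000, 2009),), true_params=truth,
            missing_rate=0.0, seed=17,
        )
        ds = t.simulate_dataset(cfg)
        design = t.ModelDesign("lek", "grass", "3km")
        data = t.FitData.from_dataset(ds, design)
        priors = t.PriorConfig(sigma_fixed=0.0)
        res = {}
        for mode in ("marginalized", "sampled"):
            mc = t.McmcConfig(
                n_chains=2, burn_in=6000, n_saved=3000, seed=11, latent_n=mode
            )
            s = t.sample_posterior(design, data, priors=priors, config=mc)
            res[mode] = s
        import arviz as az

        for name in ("p", "r", "beta0"):
            a, b = res["marginalized"], res["sampled"]
            mcse = np.sqrt(
                np.var(a.pooled(name)) / float(az.ess(a.draws[name]))
                + np.var(b.pooled(name)) / float(az.ess(b.draws[name]))
            )
            diff = abs(np.mean(a.pooled(name)) - np.mean(b.pooled(name)))
            assert diff < 5 * mcse + 0.01


class TestPredictMissing:
    def test_empty_when_nothing_missing(self):
        data = flat_fit_data(n=30)
        mc = t.McmcConfig(n_chains=1, burn_in=200, n_saved=100, seed=0)
        samples = t.sample_posterior(data.design, data, config=mc)
        pred, cells = t.predict_missing(samples, data)
        assert pred.size == 0 and len(cells) == 0

    def test_analytic_reduction_with_no_effects(self):
        # constant draws, no covariate effects: predictive mean ~ exp(beta0)
        n_draws, n_miss = 4000, 6
        draws = {
            "beta0": np.full((1, n_draws), np.log(7.0)),
            "beta1": np.zeros((1, n_draws)),
            "beta2": np.zeros((1, n_draws)),
            "beta3": np.zeros((1, n_draws)),
            "beta4": np.zeros((1, n_draws)),
            "beta5": np.zeros((1, n_draws)),
            "delta": np.zeros((1, n_draws)),
            "phi": np.zeros((1, n_draws)),
            "r": np.full((1, n_draws), 50.0),
            "sigma": np.zeros((1, n_draws)),
        }
        samples = t.PosteriorSamples(draws=draws, meta={})
        data = FitData(
            design=t.ModelDesign("direct", "grass", "3km"),
            y=np.array([5]),
            weather_x=np.zeros((1, 4)),
            hinge_x=np.zeros(1),
            cells=pd.DataFrame({"route_id": [0], "year": [2000], "climate_region": [0]}),
            missing_weather_x=np.zeros((n_miss, 4)),
            missing_hinge_x=np.zeros(n_miss),
            missing_cells=pd.DataFrame({"route_id": np.arange(n_miss), "year": 2001}),
        )
        pred, cells = t.predict_missing(samples, data, rng=0)
        assert pred.shape == (n_draws, n_miss)
        se = np.sqrt((7 + 49 / 50) / (n_draws * n_miss))
        assert abs(pred.mean() - 7.0) < 4 * se

    def test_exchangeable_missing_cell_matches_observed(self, small_direct_dataset):
        # a missing route-year with the same covariates as an observed one
        # should predict (in mean) near that cell's posterior mean of mu
        design = t.ModelDesign("direct", "grass", "3km")
        data = t.FitData.from_dataset(small_direct_dataset, design)
        if data.missing_cells is None:
            pytest.skip("fixture produced no missing route-years")
        mc = t.McmcConfig(n_chains=1, burn_in=1500, n_saved=1000, seed=2)
        samples = t.sample_posterior(design, data, config=mc)
        pred, cells = t.predict_missing(samples, data, rng=1)
        assert pred.shape[1] == len(cells)
        assert np.all(pred >= 0)


class TestPriorReadings:
    def test_scale_interpretations(self):
        assert t.PriorConfig(scale_interpretation="sd").effective_sd(10.0) == 10.0
        assert t.PriorConfig(scale_interpretation="variance").effective_sd(10.0) == pytest.approx(
            np.sqrt(10.0)
        )
        assert t.PriorConfig(scale_interpretation="precision").effective_sd(10.0) == pytest.approx(
            1 / np.sqrt(10.0)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            t.PriorConfig(scale_interpretation="log")
        with pytest.raises(ValueError):
            t.PriorConfig(phi_bounds=(2.0, 1.0))
        with pytest.raises(ValueError):
            t.McmcConfig(n_chains=0)
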