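"""Synthetic-data generator tests: determinism, generative moments,
detection bounds and contract-period structure."""

import numpy as np
import pandas as pd
import pytest

import thresholdnmix as t


def config(**kw):
    defaults = dict(
        n_routes=8,
        year_start=2000,
        year_end=2007,
        n_visits=1,
        n_climate_regions=3,
        contract_periods=((2000, 2003), (2004, 2007)),
        missing_rate=0.0,
        seed=1,
    )
    defaults.update(kw)
    return t.SimulationConfig(**defaults)


class TestConfigValidation:
    def test_rejects_bad_settings(self):
        with pytest.raises(ValueError):
            config(n_visits=0)
        with pytest.raises(ValueError):
            config(missing_rate=1.0)
        with pytest.raises(ValueError):
            config(year_start=2005, year_end=2000)
        with pytest.raises(ValueError):
            config(contract_periods=((2000, 2004), (2003, 2007)))  # overlap
        with pytest.raises(ValueError):
            config(contract_periods=((2000, 2002),))  # years uncovered


class TestWeather:
    def test_deterministic_under_seed(self):
        w1 = t.simulate_weather(config(seed=9))
        w2 = t.simulate_weather(config(seed=9))
        pd.testing.assert_frame_equal(w1, w2)

    def test_noise_free_july_tmax_equals_seasonal_mean(self):
        wp = t.WeatherParams(
            tmax_noise=0, tmin_noise=0, pdsi_sd=0, pcp_noise=0, region_sd=0
        )
        w = t.simulate_weather(config(weather=wp))
        july = w[w["month"] == 7]
        np.testing.assert_allclose(july["tmax"], wp.tmax_mean + wp.tmax_amp)

    def test_seasonal_shape(self):
        w = t.simulate_weather(config(seed=3))
        monthly_tmax = w.groupby("month")["tmax"].mean()
        assert monthly_tmax.loc[[6, 7, 8]].mean() > monthly_tmax.loc[[12, 1, 2]].mean()
        monthly_tmin = w.groupby("month")["tmin"].mean()
        assert monthly_tmin.loc[[12, 1, 2]].mean() < monthly_tmin.loc[[6, 7, 8]].mean()

    def test_region_means_converge_to_configured(self):
        # 10 regions x 40 years; no region offsets so every region shares the mean
        wp = t.WeatherParams(region_sd=0.0, pdsi_ar=0.0)
        cfg = config(
            n_climate_regions=10, year_start=1975, year_end=2014,
            contract_periods=((1975, 2014),), weather=wp,
        )
        w = t.simulate_weather(cfg)
        for region, grp in w.groupby("region"):
            n = len(grp)
            se = wp.pdsi_sd / np.sqrt(n)
            assert abs(grp["pdsi"].mean() - wp.pdsi_mean) < 3 * se  # 3 standard errors

    def test_empty_year_range_rejected(self):
        with pytest.raises(ValueError):
            config(year_start=2005, year_end=2004)


class TestLandcover:
    def test_one_value_per_route_and_period(self):
        lc = t.simulate_landcover_covariates(config())
        assert len(lc) == 8 * 2
        assert set(lc.columns) >= {"route_id", "period_start", "period_end", "grass_pct", "edge_density"}

    def test_single_period(self):
        lc = t.simulate_landcover_covariates(config(contract_periods=((2000, 2007),)))
        assert lc.groupby("route_id").size().eq(1).all()

    def test_degenerate_range(self):
        lc = t.simulate_landcover_covariates(config(grass_range=(40.0, 40.0)))
        np.testing.assert_allclose(lc["grass_pct"], 40.0)

    def test_values_within_ranges(self):
        cfg = config(grass_range=(20, 90), ed_range=(5, 60))
        lc = t.simulate_landcover_covariates(cfg)
        assert lc["grass_pct"].between(20, 90).all()
        assert lc["edge_density"].between(5, 60).all()


class TestCounts:
    def test_bitwise_determinism(self):
        d1 = t.simulate_dataset(config(seed=5))
        d2 = t.simulate_dataset(config(seed=5))
        pd.testing.assert_frame_equal(d1.counts, d2.counts)
        assert d1.truth == d2.truth

    def test_perfect_detection_copies_latent(self):
        tp = t.ThresholdModelParams(beta0=np.log(8), r=4.0, p=1.0)
        ds = t.simulate_dataset(config(n_visits=2, true_params=tp))
        latent = np.asarray(ds.truth["latent_n"])
        wide = ds.counts.pivot_table(index=["route_id", "year"], columns="visit", values="count")
        for (rid, yr), row in wide.iterrows():
            idx = ds.covariates[
                (ds.covariates["route_id"] == rid) & (ds.covariates["year"] == yr)
            ].index[0]
            assert row[1] == row[2] == latent[idx]

    def test_detection_bound(self):
        tp = t.ThresholdModelParams(beta0=np.log(10), r=2.0, p=0.6, sigma=0.2)
        ds = t.simulate_dataset(config(n_visits=2, true_params=tp, seed=8))
        latent = np.asarray(ds.truth["latent_n"])
        for (rid, yr), grp in ds.counts.groupby(["route_id", "year"]):
            idx = ds.covariates[
                (ds.covariates["route_id"] == rid) & (ds.covariates["year"] == yr)
            ].index[0]
            assert grp["count"].max() <= latent[idx]

    def test_mean_matches_analytic_in_null_model(self):
        # all effects zero, huge r: counts ~ Poisson(5); check the MC mean
        tp = t.ThresholdModelParams(beta0=np.log(5), r=1e6)
        cfg = config(
            n_routes=500, year_start=2000, year_end=2019,
            contract_periods=((2000, 2019),), true_params=tp, seed=10,
        )
        ds = t.simulate_dataset(cfg)
        n = len(ds.counts)
        assert n == 10000
        se = np.sqrt(5.0 / n)
        assert abs(ds.counts["count"].mean() - 5.0) < 3 * se

    def test_variance_matches_negbin(self):
        tp = t.ThresholdModelParams(beta0=np.log(6), r=2.0)
        cfg = config(
            n_routes=400, year_start=2000, year_end=2019,
            contract_periods=((2000, 2019),), true_params=tp,
            grass_range=(50, 50.0001), seed=12,
        )
        ds = t.simulate_dataset(cfg)
        mu = 6.0
        var = ds.counts["count"].var()
        assert var == pytest.approx(mu + mu**2 / 2.0, rel=0.1)

    def test_no_hinge_when_delta_zero(self):
        tp = t.ThresholdModelParams(beta0=1.0, beta5=0.5, delta=0.0, phi=0.3)
        ds = t.simulate_dataset(config(true_params=tp))
        z = np.asarray(ds.truth["z"])
        x = ds.covariates["hinge_natural_std"].to_numpy()
        xw = ds.covariates[
            ["pdsi_summer_std", "pcp_winter_std", "tmax_summer_std", "tmin_winter_std"]
        ].to_numpy()
        resid = z - xw @ tp.beta_weather
        coeffs = np.polyfit(x, resid, 1)
        fitted = np.polyval(coeffs, x)
        np.testing.assert_allclose(resid, fitted, atol=1e-9)

    def test_missingness_rate(self):
        cfg = config(n_routes=100, missing_rate=0.3, seed=2)
        ds = t.simulate_dataset(cfg)
        frac = 1 - ds.covariates["observed"].mean()
        assert frac == pytest.approx(0.3, abs=0.05)


class TestRasterFixture:
    def test_patterns(self):
        assert t.make_raster_fixture(10, 10, "all_grass").is_class("grassland").sum() == 100
        single = t.make_raster_fixture(9, 9, "single_cell")
        assert single.is_class("grassland").sum() == 1
        assert single.is_class("grassland")[4, 4]
        with pytest.raises(ValueError):
            t.make_raster_fixture(5, 5, "swirl")

    def test_random_density(self):
        ras = t.make_raster_fixture(100, 100, "random", seed=0, density=0.5)
        frac = ras.is_class("grassland").mean()
        se = np.sqrt(0.25 / 10000)
        assert abs(frac - 0.5) < 3 * se

    def test_deterministic(self):
        a = t.make_raster_fixture(20, 20, "random", seed=7)
        b = t.make_raster_fixture(20, 20, "random", seed=7)
        np.testing.assert_array_equal(a.classes, b.classes)


class TestWriteDataset:
    def test_files_written_and_valid(self, tmp_path):
        ds = t.simulate_dataset(config(seed=4))
        t.write_dataset(ds, tmp_path)
        for name in ("counts.csv", "weather.csv", "covariates.csv", "truth.json"):
            assert (tmp_path / name).exists()
        failures = t.validate_inputs(
            tmp_path / "counts.csv", tmp_path / "weather.csv", tmp_path / "covariates.csv",
            contract_periods=((2000, 2003), (2004, 2007)),
        )
        assert failures == []
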