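"""Covariate-window, contract-period and standardization tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

import thresholdnmix as t
from thresholdnmix.covariates import build_covariate_table

from conftest import make_weather


def weather_with_summer(region, year, pdsi=(0, 0, 0), tmax=(30, 30, 30)):
    recs = []
    for m, pd_v, tm in zip((6, 7, 8), pdsi, tmax):
        recs.append((region, year, m, pd_v, tm, 0.0, 0.0))
    return make_weather(recs)


class TestWeatherWindows:
    @pytest.mark.parametrize(
        "pdsi,expected", [((-2, -3, -1), -2.0), ((0, 0, 0), 0.0), ((1.2, 0.3, -0.6), 0.3)]
    )
    def test_summer_drought_mean(self, pdsi, expected):
        w = weather_with_summer("r1", 1998, pdsi=pdsi)
        assert t.summer_drought(w, "r1", 1999) == pytest.approx(expected)

    @pytest.mark.parametrize("tmax,expected", [((33, 38, 36), 38.0), ((35, 35, 35), 35.0)])
    def test_summer_tmax_max(self, tmax, expected):
        w = weather_with_summer("r1", 1998, tmax=tmax)
        assert t.summer_tmax(w, "r1", 1999) == pytest.approx(expected)

    def test_one_year_lag(self):
        # survey year 2000 must read the 1999 summer, not 2000's
        recs = [("r1", 1999, m, 1.0, 20.0, 0, 0) for m in (6, 7, 8)]
        recs += [("r1", 2000, m, 9.0, 45.0, 0, 0) for m in (6, 7, 8)]
        w = make_weather(recs)
        assert t.summer_drought(w, "r1", 2000) == pytest.approx(1.0)
        assert t.summer_tmax(w, "r1", 2000) == pytest.approx(20.0)

    def test_winter_window_spans_calendar_years(self):
        # December of year-1 plus January/February of the survey year
        recs = [
            ("r1", 1999, 12, 0, 0, -12.0, 30.0),
            ("r1", 2000, 1, 0, 0, -15.0, 10.0),
            ("r1", 2000, 2, 0, 0, -8.0, 20.0),
            ("r1", 2000, 12, 0, 0, -40.0, 99.0),  # outside the window
        ]
        w = make_weather(recs)
        assert t.winter_tmin(w, "r1", 2000) == pytest.approx(-15.0)
        assert t.winter_precip(w, "r1", 2000) == pytest.approx(20.0)

    @pytest.mark.parametrize("pcp,expected", [((0, 0, 0), 0.0), ((12.4, 31.0, 7.6), 17.0)])
    def test_winter_precip_mean(self, pcp, expected):
        recs = [
            ("r1", 1999, 12, 0, 0, -1, pcp[0]),
            ("r1", 2000, 1, 0, 0, -1, pcp[1]),
            ("r1", 2000, 2, 0, 0, -1, pcp[2]),
        ]
        assert t.winter_precip(make_weather(recs), "r1", 2000) == pytest.approx(expected)

    def test_missing_month_gives_nan_not_imputation(self):
        w = weather_with_summer("r1", 1998)
        w = w[w["month"] != 7]
        assert np.isnan(t.summer_drought(w, "r1", 1999))
        assert np.isnan(t.summer_tmax(w, "r1", 1999))

    def test_data_outside_window_is_irrelevant(self):
        base = weather_with_summer("r1", 1998, pdsi=(1, 2, 3))
        noisy = pd.concat(
            [base, make_weather([("r1", 1996, m, 99, 99, 99, 99) for m in range(1, 13)])]
        )
        assert t.summer_drought(noisy, "r1", 1999) == t.summer_drought(base, "r1", 1999)


class TestContractPeriods:
    def test_year_maps_to_containing_period(self):
        periods = [(1996, 2005), (2006, 2010)]
        assert t.assign_contract_period(1999, periods) == (1996, 2005)
        assert t.assign_contract_period(2006, periods) == (2006, 2010)

    def test_boundary_years_inclusive(self):
        assert t.assign_contract_period(1996, [(1996, 2005)]) == (1996, 2005)
        assert t.assign_contract_period(2005, [(1996, 2005)]) == (1996, 2005)

    def test_uncovered_year_raises_with_year_named(self):
        with pytest.raises(ValueError, match="1990"):
            t.assign_contract_period(1990, [(1996, 2005)])


class TestStandardizer:
    def test_symmetric_triple(self):
        s = t.Standardizer.fit([1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.transform([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 3, size=200)
        z = t.Standardizer.fit(vals).transform(vals)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30))
    def test_round_trip(self, values):
        arr = np.asarray(values)
        assume(len(np.unique(arr)) >= 2 and np.std(arr, ddof=1) > 0)
        s = t.Standardizer.fit(values)
        back = s.inverse(s.transform(values))
        np.testing.assert_allclose(back, values, rtol=1e-9, atol=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            t.Standardizer.fit([4.0, 4.0, 4.0])


def varying_weather(regions, years):
    """Complete monthly records whose values differ by year (so that
    standardization over any two survey years is well defined)."""
    recs = []
    for region in regions:
        for yr in years:
            for m in range(1, 13):
                v = 0.1 * (yr - 1990)
                recs.append((region, yr, m, v, 20.0 + v, -5.0 - v, 15.0 + v))
    return make_weather(recs)


class TestVectorizedWindows:
    def test_matches_scalar_window_functions(self):
        from thresholdnmix.covariates import _weather_covariate_table

        rng = np.random.default_rng(5)
        recs = []
        for region in ("a", "b"):
            for yr in range(1998, 2003):
                for m in range(1, 13):
                    if rng.random() < 0.05:
                        continue  # leave holes to exercise the missing path
                    recs.append((region, yr, m, *rng.normal(size=4)))
        w = make_weather(recs)
        tab = _weather_covariate_table(w)
        for _, row in tab.iterrows():
            reg, yr = row["climate_region"], int(row["year"])
            for col, fn in [
                ("pdsi_summer", t.summer_drought),
                ("tmax_summer", t.summer_tmax),
                ("tmin_winter", t.winter_tmin),
                ("pcp_winter", t.winter_precip),
            ]:
                assert np.isclose(row[col], fn(w, reg, yr), equal_nan=True)


class TestBuildCovariateTable:
    def test_missing_rows_flagged_not_dropped(self):
        cells = pd.DataFrame(
            {
                "route_id": [0, 0, 1, 1],
                "year": [1999, 2000, 1999, 2000],
                "climate_region": ["r1", "r1", "r2", "r2"],
            }
        )
        weather = varying_weather(["r1", "r2"], (1998, 1999, 2000))
        # remove July 1999 in r1 -> route 0's survey year 2000 loses its lagged summer
        weather = weather[
            ~((weather["region"] == "r1") & (weather["year"] == 1999) & (weather["month"] == 7))
        ]
        landcover = pd.DataFrame(
            {
                "route_id": [0, 1],
                "period_start": [1996, 1996],
                "period_end": [2005, 2005],
                "grass_pct": [55.0, 30.0],
                "edge_density": [20.0, 40.0],
            }
        )
        tab, _ = build_covariate_table(cells, weather, landcover, [(1996, 2005)])
        assert len(tab) == 4  # flagged, not dropped
        flagged = tab[(tab["route_id"] == 0) & (tab["year"] == 2000)]["missing"].iloc[0]
        assert flagged
        assert not tab[(tab["route_id"] == 0) & (tab["year"] == 1999)]["missing"].iloc[0]

    def test_landcover_paired_through_contract_period(self):
        cells = pd.DataFrame(
            {"route_id": [0, 0], "year": [1999, 2007], "climate_region": ["r1", "r1"]}
        )
        weather = varying_weather(["r1"], (1998, 1999, 2006, 2007))
        landcover = pd.DataFrame(
            {
                "route_id": [0, 0],
                "period_start": [1996, 2006],
                "period_end": [2005, 2010],
                "grass_pct": [55.0, 30.0],
                "edge_density": [20.0, 40.0],
            }
        )
        tab, _ = build_covariate_table(cells, weather, landcover, [(1996, 2005), (2006, 2010)])
        assert tab[tab["year"] == 1999]["hinge_natural"].iloc[0] == 55.0
        assert tab[tab["year"] == 2007]["hinge_natural"].iloc[0] == 30.0
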