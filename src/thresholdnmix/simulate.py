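"""Synthetic survey data with the structure the analysis assumes.

The generator emulates route-level game-bird count surveys: a panel of
routes observed over a span of breeding seasons (twice per season for
lek designs, once for auditory designs), monthly weather series per
climate region, and land-cover covariates constant within Conservation
Reserve Program contract periods.  Counts come from the exact
generative model the fitter assumes — negative binomial latent
abundance with a piecewise-linear (hinge) covariate effect, optionally
thinned by binomial detection — under known parameters, so parameter
recovery can be checked against the recorded truth.

Counts are simulated at route level (survey stops pre-summed), matching
how the analysis treats the data.  Missingness is applied completely at
random to route-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import build_covariate_table, Standardizer
from .landscape import LandCoverRaster
from .model import linear_predictor, nb_success
from .params import ThresholdModelParams

__all__ = [
    "WeatherParams",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_weather",
    "simulate_landcover_covariates",
    "simulate_counts",
    "simulate_dataset",
    "make_raster_fixture",
    "write_dataset",
]


@dataclass
class WeatherParams:
    """Moments of the synthetic monthly weather process.

    Temperatures are in deg C, precipitation in mm/month, PDSI in index
    units.  TMAX and TMIN share a seasonal cosine peaking in July, so
    June-August is the warm season and December-February the cold one.
    ``region_sd`` spreads region-level mean offsets; ``*_noise`` are
    month-to-month standard deviations.
    """

    tmax_mean: float = 26.0
    tmax_amp: float = 12.0
    tmax_noise: float = 1.5
    tmin_mean: float = 2.0
    tmin_amp: float = 14.0
    tmin_noise: float = 2.0
    pdsi_mean: float = 0.0
    pdsi_sd: float = 2.0
    pdsi_ar: float = 0.8
    pcp_mean: float = 55.0
    pcp_amp: float = 30.0
    pcp_noise: float = 12.0
    region_sd: float = 1.0


@dataclass
class SimulationConfig:
    """Design of one synthetic study.

    Defaults mirror a mid-sized statewide survey program: 33 routes over
    1996-2014, 9 climate regions, two Conservation Reserve Program
    contract periods, and roughly one route-year in ten unsurveyed.
    """

    n_routes: int = 33
    year_start: int = 1996
    year_end: int = 2014
    n_visits: int = 2
    n_climate_regions: int = 9
    contract_periods: tuple = ((1996, 2005), (2006, 2014))
    true_params: ThresholdModelParams = field(default_factory=ThresholdModelParams)
    hinge: str = "grass"
    grass_range: tuple = (20.0, 95.0)
    ed_range: tuple = (5.0, 80.0)
    missing_rate: float = 0.1
    weather: WeatherParams = field(default_factory=WeatherParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        for lo, hi in (self.grass_range, self.ed_range):
            if not lo <= hi:
                raise ValueError("covariate range min must be <= max")
        periods = sorted((int(a), int(b)) for a, b in self.contract_periods)
        for (a0, b0), (a1, b1) in zip(periods, periods[1:]):
            if a1 <= b0:
                raise ValueError("contract periods must be disjoint")
        covered = set()
        for a, b in periods:
            covered.update(range(a, b + 1))
        if not set(range(self.year_start, self.year_end + 1)) <= covered:
            raise ValueError("contract periods must cover every survey year")

    @property
    def years(self):
        return range(self.year_start, self.year_end + 1)


@dataclass
class SyntheticDataset:
    """A simulated study: observed tables plus the generating truth."""

    counts: pd.DataFrame           # route_id, year, visit, count, climate_region
    weather: pd.DataFrame          # region, year, month, pdsi, tmax, tmin, pcp
    landcover: pd.DataFrame        # route_id, period_start, period_end, grass_pct, edge_density
    covariates: pd.DataFrame       # built covariate table (natural + standardized)
    standardizers: dict            # covariate name -> Standardizer
    truth: dict                    # params, latent N, epsilon per route-year cell
    config: SimulationConfig

    @property
    def cells(self) -> pd.DataFrame:
        """Route-year grid (observed and unobserved) with covariates."""
        return self.covariates


def simulate_weather(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monthly PDSI/TMAX/TMIN/PCP per climate region.

    Generates from one year before the first survey year (the lagged
    summer windows need it) through the last survey year.  Deterministic
    under the config seed.
    """
    if config.n_climate_regions < 1:
        raise ValueError("need at least one climate region")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wp = config.weather
    years = np.arange(config.year_start - 1, config.year_end + 1)
    months = np.arange(1, 13)
    rows = []
    for region in range(config.n_climate_regions):
        off_tmax, off_tmin, off_pcp = rng.normal(0.0, wp.region_sd, size=3)
        pdsi_prev = rng.normal(wp.pdsi_mean, wp.pdsi_sd) if wp.pdsi_sd > 0 else wp.pdsi_mean
        for year in years:
            season = np.cos(2 * np.pi * (months - 7) / 12.0)
            tmax = wp.tmax_mean + off_tmax + wp.tmax_amp * season + rng.normal(0, wp.tmax_noise, 12)
            tmin = wp.tmin_mean + off_tmin + wp.tmin_amp * season + rng.normal(0, wp.tmin_noise, 12)
            pcp = np.maximum(
                wp.pcp_mean + off_pcp + wp.pcp_amp * season + rng.normal(0, wp.pcp_noise, 12), 0.0
            )
            pdsi = np.empty(12)
            innov_sd = wp.pdsi_sd * np.sqrt(max(1.0 - wp.pdsi_ar**2, 0.0))
            for m in range(12):
                pdsi_prev = (
                    wp.pdsi_mean
                    + wp.pdsi_ar * (pdsi_prev - wp.pdsi_mean)
                    + (rng.normal(0, innov_sd) if innov_sd > 0 else 0.0)
                )
                pdsi[m] = pdsi_prev
            for m in range(12):
                rows.append(
                    {
                        "region": region,
                        "year": int(year),
                        "month": int(m + 1),
                        "pdsi": pdsi[m],
                        "tmax": tmax[m],
                        "tmin": tmin[m],
                        "pcp": pcp[m],
                    }
                )
    return pd.DataFrame(rows)


def simulate_landcover_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None, rho: float = 0.0
) -> pd.DataFrame:
    """Per-route, per-contract-period grassland percent and edge density.

    Values are drawn uniformly within the configured natural-unit ranges
    and held constant within a contract period.  ``rho`` adds optional
    within-route persistence across consecutive periods (0 = independent
    redraws each period).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    periods = sorted((int(a), int(b)) for a, b in config.contract_periods)
    rows = []
    for rid in range(config.n_routes):
        prev = None
        for start, end in periods:
            g = rng.uniform(*config.grass_range)
            e = rng.uniform(*config.ed_range)
            if prev is not None and rho > 0:
                g = rho * prev[0] + (1 - rho) * g
                e = rho * prev[1] + (1 - rho) * e
            prev = (g, e)
            rows.append(
                {
                    "route_id": rid,
                    "period_start": start,
                    "period_end": end,
                    "grass_pct": g,
                    "edge_density": e,
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(
    config: SimulationConfig,
    weather: pd.DataFrame,
    landcover: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Draw latent abundances and observed counts under the true parameters.

    Covariates are standardized with the same machinery the fitting
    pipeline uses, so the true threshold ``phi`` (standardized units)
    refers to the same scale inference sees.  With ``n_visits >= 2`` the
    observation layer is binomial thinning of the latent N; with one
    visit the count is the negative binomial draw itself.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    tp = config.true_params

    cells = pd.DataFrame(
        [
            {"route_id": rid, "year": yr, "climate_region": rid % config.n_climate_regions}
            for rid in range(config.n_routes)
            for yr in config.years
        ]
    )
    cov, standardizers = build_covariate_table(
        cells, weather, landcover, config.contract_periods, hinge=config.hinge
    )
    if cov["missing"].any():
        raise RuntimeError("simulated covariates should be complete")

    weather_x = cov[["pdsi_summer_std", "pcp_winter_std", "tmax_summer_std", "tmin_winter_std"]].to_numpy()
    hinge_x = cov["hinge_natural_std"].to_numpy()
    n = len(cov)

    eps = rng.normal(0.0, tp.sigma, size=n) if tp.sigma > 0 else np.zeros(n)
    z = linear_predictor(tp, weather_x, hinge_x, epsilon=eps)
    mu = np.exp(z)
    s = nb_success(mu, tp.r)
    latent_n = rng.negative_binomial(tp.r, s)

    observed = rng.random(n) >= config.missing_rate
    recs = []
    for idx in np.flatnonzero(observed):
        row = cov.iloc[idx]
        if config.n_visits >= 2:
            for visit in range(1, config.n_visits + 1):
                y = rng.binomial(latent_n[idx], tp.p)
                recs.append(
                    {
                        "route_id": int(row["route_id"]),
                        "year": int(row["year"]),
                        "visit": visit,
                        "count": int(y),
                        "climate_region": int(row["climate_region"]),
                    }
                )
        else:
            recs.append(
                {
                    "route_id": int(row["route_id"]),
                    "year": int(row["year"]),
                    "visit": 1,
                    "count": int(latent_n[idx]),
                    "climate_region": int(row["climate_region"]),
                }
            )
    counts = pd.DataFrame(recs)

    cov = cov.copy()
    cov["observed"] = observed
    truth = {
        "params": tp.to_dict(),
        "latent_n": latent_n.tolist(),
        "epsilon": eps.tolist(),
        "z": z.tolist(),
        "standardizers": {k: v.to_dict() for k, v in standardizers.items()},
    }
    return SyntheticDataset(
        counts=counts,
        weather=weather,
        landcover=landcover,
        covariates=cov,
        standardizers=standardizers,
        truth=truth,
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Weather + land cover + counts in one call, reproducible from the seed."""
    weather = simulate_weather(config)
    landcover = simulate_landcover_covariates(config)
    return simulate_counts(config, weather, landcover)


def make_raster_fixture(
    width: int,
    height: int,
    pattern: str,
    seed: int = 0,
    density: float = 0.5,
    block_size: int = 2,
    cell_size: float = 30.0,
) -> LandCoverRaster:
    """Small classified grids for landscape-metric tests.

    Patterns: ``all_grass``, ``single_cell`` (one grassland cell at the
    center of cropland), ``block`` (a square grassland block centered in
    cropland), ``checkerboard``, and ``random`` (iid grassland with the
    given density, cropland otherwise).
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    GRASS, CROP = 1, 2
    grid = np.full((height, width), CROP, dtype=int)
    if pattern == "all_grass":
        grid[:] = GRASS
    elif pattern == "single_cell":
        grid[height // 2, width // 2] = GRASS
    elif pattern == "block":
        r0, c0 = height // 2 - block_size // 2, width // 2 - block_size // 2
        grid[r0 : r0 + block_size, c0 : c0 + block_size] = GRASS
    elif pattern == "checkerboard":
        rr, cc = np.indices((height, width))
        grid[(rr + cc) % 2 == 0] = GRASS
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        grid[rng.random((height, width)) < density] = GRASS
    else:
        raise ValueError(f"unknown raster pattern {pattern!r}")
    return LandCoverRaster(classes=grid, cell_size=cell_size)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the CSV/JSON files the readers and CLI consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.counts.to_csv(outdir / "counts.csv", index=False)
    ds.weather.to_csv(outdir / "weather.csv", index=False)
    ds.landcover.to_csv(outdir / "covariates.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=2))
    cfg = asdict(ds.config)
    cfg["true_params"] = ds.config.true_params.to_dict()
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=2, default=str))
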