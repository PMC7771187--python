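"""Replicate simulation experiments: parameter recovery, detection
recovery, posterior-predictive calibration, and prior recovery.

These drive the whole pipeline — simulate under known parameters, fit
with MCMC, summarize — and report per-replicate credible-interval
coverage.  They are what the validation suite and the reproduction
script run; problem sizes are arguments so studies can be scaled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import FitData, McmcConfig, PriorConfig, sample_posterior
from .params import ModelDesign, ThresholdModelParams
from .posterior import bayesian_p_value
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "default_direct_truth",
    "default_lek_truth",
    "parameter_recovery",
    "detection_recovery",
    "calibration_experiment",
    "prior_recovery_draws",
]


def default_direct_truth() -> ThresholdModelParams:
    """Generating parameters for the single-visit recovery study:
    moderate weather effects, a clear negative slope change at the
    center of the grassland gradient, and mild extra heterogeneity."""
    return ThresholdModelParams(
        beta0=2.0,
        beta_weather=[0.15, -0.1, 0.0, -0.15],
        beta5=0.5,
        delta=-1.0,
        phi=0.0,
        r=2.5,
        sigma=0.1,
    )


def default_lek_truth(p: float = 0.7) -> ThresholdModelParams:
    """Generating parameters for the repeated-count detection study."""
    return ThresholdModelParams(
        beta0=2.0,
        beta_weather=[0.15, -0.1, 0.0, -0.15],
        beta5=0.4,
        delta=-0.8,
        phi=0.0,
        r=3.0,
        p=p,
        sigma=0.1,
    )


def _sim_config(truth, n_routes, n_years, n_visits, seed) -> SimulationConfig:
    y0 = 1996
    y1 = y0 + n_years - 1
    mid = y0 + n_years // 2
    return SimulationConfig(
        n_routes=n_routes,
        year_start=y0,
        year_end=y1,
        n_visits=n_visits,
        contract_periods=((y0, mid - 1), (mid, y1)),
        true_params=truth,
        missing_rate=0.05,
        seed=seed,
    )


def _covers(samples, name, true_value) -> bool:
    d = samples.pooled(name)
    lo, hi = np.quantile(d, [0.025, 0.975])
    return bool(lo <= true_value <= hi)


def parameter_recovery(
    n_reps: int = 20,
    n_routes: int = 50,
    n_years: int = 20,
    truth: ThresholdModelParams | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate simulate-and-refit study for the single-visit design.

    Each replicate simulates a fresh panel under ``truth``, refits, and
    records whether the 95% credible interval covers the true threshold,
    slopes and overdispersion, plus the threshold posterior mean error
    (standardized units).
    """
    truth = truth or default_direct_truth()
    design = ModelDesign("direct", "grass", "3km")
    rows = []
    for rep in range(n_reps):
        cfg = _sim_config(truth, n_routes, n_years, 1, seed=seed * 1000 + rep)
        ds = simulate_dataset(cfg)
        data = FitData.from_dataset(ds, design)
        mc = mcmc or McmcConfig(n_chains=2, burn_in=5000, n_saved=2000, seed=seed * 1000 + rep)
        samples = sample_posterior(design, data, config=mc)
        rows.append(
            {
                "rep": rep,
                "cover_phi": _covers(samples, "phi", truth.phi),
                "cover_beta5": _covers(samples, "beta5", truth.beta5),
                "cover_delta": _covers(samples, "delta", truth.delta),
                "cover_r": _covers(samples, "r", truth.r),
                "phi_mean": float(np.mean(samples.pooled("phi"))),
                "phi_abs_err": float(abs(np.mean(samples.pooled("phi")) - truth.phi)),
            }
        )
    return pd.DataFrame(rows)


def detection_recovery(
    n_reps: int = 10,
    n_routes: int = 30,
    n_years: int = 15,
    p_true: float = 0.7,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate study for the repeated-count (lek) design: does the 95%
    credible interval for detection probability cover the truth?"""
    truth = default_lek_truth(p=p_true)
    design = ModelDesign("lek", "grass", "3km")
    rows = []
    for rep in range(n_reps):
        cfg = _sim_config(truth, n_routes, n_years, 2, seed=7000 + seed * 1000 + rep)
        ds = simulate_dataset(cfg)
        data = FitData.from_dataset(ds, design)
        mc = mcmc or McmcConfig(n_chains=2, burn_in=1500, n_saved=800, seed=seed * 1000 + rep)
        samples = sample_posterior(design, data, config=mc)
        d = samples.pooled("p")
        lo, hi = np.quantile(d, [0.025, 0.975])
        rows.append(
            {
                "rep": rep,
                "p_mean": float(np.mean(d)),
                "p_lower95": float(lo),
                "p_upper95": float(hi),
                "cover_p": bool(lo <= p_true <= hi),
            }
        )
    return pd.DataFrame(rows)


def calibration_experiment(
    n_reps: int = 20,
    n_routes: int = 25,
    n_years: int = 12,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-predictive calibration under correct specification.

    Data simulated from the model and refit should give Bayesian
    p-values away from 0 and 1; each replicate records its p-value.
    """
    truth = default_direct_truth()
    design = ModelDesign("direct", "grass", "3km")
    rows = []
    for rep in range(n_reps):
        cfg = _sim_config(truth, n_routes, n_years, 1, seed=3000 + seed * 1000 + rep)
        ds = simulate_dataset(cfg)
        data = FitData.from_dataset(ds, design)
        mc = mcmc or McmcConfig(n_chains=2, burn_in=1500, n_saved=800, seed=seed * 1000 + rep)
        samples = sample_posterior(design, data, config=mc)
        rows.append(
            {"rep": rep, "p_value": bayesian_p_value(samples, data, rng=rep)}
        )
    return pd.DataFrame(rows)


def prior_recovery_draws(
    n_draws: int = 5000,
    thin: int = 25,
    seed: int = 0,
):
    """Sample the prior by running the sampler with the likelihood off.

    Returns the PosteriorSamples plus the PriorConfig used, for
    comparison of the sampled marginals (intercept, overdispersion,
    threshold) against their analytic prior distributions.
    """
    rng = np.random.default_rng(seed)
    n = 50
    data = FitData(
        design=ModelDesign("direct", "grass", "3km"),
        y=np.zeros(n, dtype=int),
        weather_x=rng.normal(size=(n, 4)),
        hinge_x=np.linspace(-2.0, 2.0, n),
        cells=pd.DataFrame(
            {"route_id": np.arange(n), "year": 2000, "climate_region": 0}
        ),
    )
    priors = PriorConfig()
    mc = McmcConfig(
        n_chains=1, burn_in=2000, n_saved=n_draws, thin=thin, seed=seed, store_eps=False
    )
    samples = sample_posterior(data.design, data, priors=priors, config=mc, likelihood_off=True)
    return samples, priors
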