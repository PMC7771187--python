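"""Fit the change-point abundance model to a simulated auditory survey.

Simulates 40 routes over 16 years under a known threshold response
(slope +0.5 below the threshold, -0.5 above it), fits the model with
the desk-scale MCMC protocol, and prints posterior summaries, the
threshold in natural units (percent grassland), and the evidence for a
slope change, Pr(delta < 0).
"""

import numpy as np

import thresholdnmix as t

truth = t.ThresholdModelParams(
    beta0=2.0, beta_weather=[0.15, -0.1, 0.0, -0.15],
    beta5=0.5, delta=-1.0, phi=0.0, r=2.5, sigma=0.1,
)
config = t.SimulationConfig(
    n_routes=40, year_start=1999, year_end=2014, n_visits=1,
    contract_periods=((1999, 2006), (2007, 2014)),
    true_params=truth, missing_rate=0.05, seed=11,
)
dataset = t.simulate_dataset(config)
design = t.ModelDesign("direct", "grass", "3km")
data = t.FitData.from_dataset(dataset, design)

mcmc = t.McmcConfig(n_chains=2, burn_in=6000, n_saved=2500, seed=1)
samples = t.sample_posterior(design, data, config=mcmc)

print(samples.summary().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
report = t.fit_report(samples, data, rng_seed=1)
nat = report["threshold_natural"]
print(f"\nthreshold: {nat['mean']:.1f}% grassland "
      f"(95% CRI {nat['lower95']:.1f}-{nat['upper95']:.1f}%)")
print(f"Pr(delta < 0) = {t.effect_probability(samples, 'delta', 'negative'):.3f} "
      "(evidence the slope drops after the threshold)")
print(f"Bayesian p-value = {report['bayesian_p_value']:.2f} "
      "(values near 0 or 1 would flag misfit)")
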