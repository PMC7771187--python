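"""Annual abundance index and percent-change trend from a fitted model.

Builds the posterior annual totals across routes (observed route-years
plus posterior predictions for unsurveyed ones), then expresses the
change between the first and last survey years as a total percent
change and an average per-year change.
"""

import thresholdnmix as t

truth = t.ThresholdModelParams(
    beta0=2.0, beta_weather=[0.15, -0.1, 0.0, -0.15],
    beta5=0.5, delta=-1.0, phi=0.0, r=2.5, sigma=0.1,
)
config = t.SimulationConfig(
    n_routes=25, year_start=2000, year_end=2011, n_visits=1,
    contract_periods=((2000, 2005), (2006, 2011)),
    true_params=truth, missing_rate=0.1, seed=42,
)
dataset = t.simulate_dataset(config)
design = t.ModelDesign("direct", "grass", "3km")
data = t.FitData.from_dataset(dataset, design)
samples = t.sample_posterior(
    design, data, config=t.McmcConfig(n_chains=2, burn_in=2000, n_saved=1000, seed=7)
)

index = t.abundance_index(samples, data, rng=0)
print(index.table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

total, per_year = t.percent_change(index, 2000, 2011)
direction = "decline" if total > 0 else "increase"
print(f"\ntotal {direction}: {abs(total):.1f}% over {2011 - 2000} years "
      f"({abs(per_year):.1f}% per year on average)")
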