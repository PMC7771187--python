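import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import thresholdnmix as t

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_weather(records):
    """Weather frame from (region, year, month, pdsi, tmax, tmin, pcp) tuples."""
    return pd.DataFrame(
        records, columns=["region", "year", "month", "pdsi", "tmax", "tmin", "pcp"]
    )


@pytest.fixture(scope="session")
def small_direct_dataset():
    truth = t.ThresholdModelParams(
        beta0=2.0,
        beta_weather=[0.15, -0.1, 0.0, -0.15],
        beta5=0.5,
        delta=-1.0,
        phi=0.0,
        r=2.5,
        sigma=0.1,
    )
    cfg = t.SimulationConfig(
        n_routes=25,
        year_start=2000,
        year_end=2011,
        n_visits=1,
        contract_periods=((2000, 2005), (2006, 2011)),
        true_params=truth,
        missing_rate=0.1,
        seed=42,
    )
    return t.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_direct_fit(small_direct_dataset):
    """One shared desk-scale fit reused by the posterior-summary tests."""
    design = t.ModelDesign("direct", "grass", "3km")
    data = t.FitData.from_dataset(small_direct_dataset, design)
    mc = t.McmcConfig(n_chains=2, burn_in=2000, n_saved=1000, seed=7)
    samples = t.sample_posterior(design, data, config=mc)
    return data, samples
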