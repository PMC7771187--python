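"""Posterior summaries: effect probabilities, thresholds in natural units,
goodness-of-fit, annual abundance indices and percent-change trends.

Direction probabilities for the regression coefficients are the share
of pooled posterior draws strictly above (or below) zero; the same
computation on the intensification coefficient quantifies the evidence
for a threshold response.  The threshold itself is reported back on the
natural covariate scale (percent grassland, or edge density in m/ha)
via the stored standardization statistics.

The Bayesian p-value is a posterior-predictive check: for each saved
draw, replicate counts are simulated under that draw's parameters at
the observed covariates, and the p-value averages the probability that
the observed data exceed the replicates (ties count one half).  Values
near 0 or 1 flag misfit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import Standardizer
from .mcmc import PosteriorSamples, FitData, gelman_rubin, predict_missing

__all__ = [
    "EffectReport",
    "AbundanceIndex",
    "effect_probability",
    "threshold_summary",
    "bayesian_p_value",
    "abundance_index",
    "percent_change",
    "fit_report",
]


@dataclass
class EffectReport:
    parameter: str
    mean: float
    lower95: float
    upper95: float
    pr_positive: float
    pr_negative: float


@dataclass
class AbundanceIndex:
    """Posterior annual totals across routes (mean and 95% CRI per year)."""

    table: pd.DataFrame  # year, mean, lower95, upper95
    omitted_years: list = field(default_factory=list)

    def mean_for(self, year: int) -> float:
        row = self.table[self.table["year"] == year]
        if row.empty:
            raise KeyError(f"year {year} not in the index")
        return float(row["mean"].iloc[0])


def effect_probability(samples: PosteriorSamples, parameter: str, direction: str) -> float:
    """Fraction of pooled draws strictly above ('positive') or below
    ('negative') zero."""
    draws = samples.pooled(parameter)
    if direction == "positive":
        return float(np.mean(draws > 0))
    if direction == "negative":
        return float(np.mean(draws < 0))
    raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


def threshold_summary(samples: PosteriorSamples, standardizer: Standardizer | None = None) -> dict:
    """Threshold location back-transformed to natural covariate units.

    Each standardized draw maps through ``natural = draw * sd + mean``;
    quantiles commute with this affine map, so the CRI endpoints are the
    transformed endpoints.
    """
    if standardizer is None:
        stds = samples.meta.get("standardizers", {})
        standardizer = stds.get("hinge_natural")
    if standardizer is None:
        raise ValueError("no standardization statistics available for the hinge covariate")
    nat = standardizer.inverse(samples.pooled("phi"))
    return {
        "mean": float(np.mean(nat)),
        "lower95": float(np.quantile(nat, 0.025)),
        "upper95": float(np.quantile(nat, 0.975)),
        "mean_std": float(np.mean(samples.pooled("phi"))),
    }


def _draw_mu(samples, data, d, eps=None):
    hx = data.hinge_x
    diff = hx - samples.pooled("phi")[d]
    slope = samples.pooled("beta5")[d] + samples.pooled("delta")[d] * (diff >= 0)
    bw = np.array([samples.pooled(f"beta{i}")[d] for i in (1, 2, 3, 4)])
    z = samples.pooled("beta0")[d] + data.weather_x @ bw + slope * diff
    if eps is not None:
        z = z + eps
    return np.exp(z)


def _pooled_eps(samples):
    if "eps" not in samples.draws:
        return None
    e = samples.draws["eps"]
    return e.reshape(-1, e.shape[-1])


def bayesian_p_value(
    samples: PosteriorSamples,
    data: FitData,
    rng: np.random.Generator | int | None = 0,
    max_draws: int = 500,
) -> float:
    """Posterior-predictive p-value; ties contribute one half.

    Uses at most ``max_draws`` evenly spaced pooled draws.  For the lek
    design the replicate is a fresh latent N followed by binomial visit
    counts; for the direct design it is a fresh negative binomial count.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lek = data.design.observation == "lek"
    r_draws = samples.pooled("r")
    n_pool = len(r_draws)
    idx = np.unique(np.linspace(0, n_pool - 1, min(max_draws, n_pool)).astype(int))
    eps_all = _pooled_eps(samples)

    exceed = 0.0
    count = 0
    for d in idx:
        eps = eps_all[d] if eps_all is not None else None
        mu = _draw_mu(samples, data, d, eps)
        r = r_draws[d]
        s = r / (r + mu)
        if lek:
            p = samples.pooled("p")[d]
            N_rep = rng.negative_binomial(r, s)
            y_rep = rng.binomial(N_rep[:, None], p, size=data.y.shape)
        else:
            y_rep = rng.negative_binomial(r, s)
        obs = data.y
        exceed += np.sum(obs > y_rep) + 0.5 * np.sum(obs == y_rep)
        count += obs.size
    return float(exceed / count)


def _latent_n_draw(samples, data, d, eps, rng):
    """One draw of latent N | y, params for every observed lek route-year."""
    mu = _draw_mu(samples, data, d, eps)
    r = samples.pooled("r")[d]
    p = samples.pooled("p")[d]
    s = r / (r + mu)
    y = data.y
    ymax = y.max(axis=1)
    if p >= 1.0:
        return ymax.copy()
    from scipy.special import gammaln

    T = int(np.max(mu + (12 + 21 / np.sqrt(r)) * np.sqrt(mu + mu * mu / r)) + 40)
    T = max(T, int(ymax.max()) + 1)
    ns = np.arange(T + 1).astype(float)
    log_nb = (
        gammaln(ns[None, :] + r)
        - gammaln(r)
        - gammaln(ns[None, :] + 1)
        + r * np.log(s)[:, None]
        + ns[None, :] * np.log1p(-s)[:, None]
    )
    log_bin = np.zeros_like(log_nb)
    for j in range(y.shape[1]):
        yj = y[:, j].astype(float)
        diff = ns[None, :] - yj[:, None]
        with np.errstate(invalid="ignore"):
            t = (
                gammaln(ns[None, :] + 1)
                - gammaln(yj + 1)[:, None]
                - gammaln(diff + 1)
            )
        log_bin += np.where(diff >= 0, t + yj[:, None] * np.log(p) + diff * np.log1p(-p), -np.inf)
    logw = log_nb + log_bin
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    cdf = np.cumsum(w, axis=1)
    u = rng.random(size=len(mu))
    return (u[:, None] <= cdf).argmax(axis=1)


def abundance_index(
    samples: PosteriorSamples,
    data: FitData,
    rng: np.random.Generator | int | None = 0,
    max_draws: int = 400,
) -> AbundanceIndex:
    """Posterior annual abundance totals summed across routes.

    Observed lek route-years contribute a latent-N draw (resampled from
    N | y, params per posterior draw); observed direct route-years
    contribute the draw's expected count mu (an index of abundance, not
    detection-corrected abundance); unsurveyed route-years contribute
    posterior-predictive draws from the latent process.  Years with no
    covariate-complete route-years are omitted and listed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lek = data.design.observation == "lek"
    n_pool = len(samples.pooled("r"))
    idx = np.unique(np.linspace(0, n_pool - 1, min(max_draws, n_pool)).astype(int))
    eps_all = _pooled_eps(samples)

    years_obs = data.cells["year"].to_numpy()
    miss_pred, miss_cells = predict_missing(samples, data, rng=rng)
    years_miss = (
        miss_cells["year"].to_numpy() if len(miss_cells) else np.array([], dtype=int)
    )
    all_years = np.unique(np.concatenate([years_obs, years_miss]))

    totals = np.zeros((len(idx), len(all_years)))
    for k, d in enumerate(idx):
        eps = eps_all[d] if eps_all is not None else None
        if lek:
            contrib = _latent_n_draw(samples, data, d, eps, rng).astype(float)
        else:
            contrib = _draw_mu(samples, data, d, eps)
        for yi, yr in enumerate(all_years):
            tot = contrib[years_obs == yr].sum()
            if len(years_miss):
                tot += miss_pred[d][years_miss == yr].sum()
            totals[k, yi] = tot

    table = pd.DataFrame(
        {
            "year": all_years,
            "mean": totals.mean(axis=0),
            "lower95": np.quantile(totals, 0.025, axis=0),
            "upper95": np.quantile(totals, 0.975, axis=0),
        }
    )
    return AbundanceIndex(table=table, omitted_years=[])


def percent_change(index: AbundanceIndex, year0: int, year1: int) -> tuple[float, float]:
    """Total percent change between two index years, and the average
    per-year change (total divided by the year span).

    A positive total means a decline (the baseline exceeds the later
    year), matching how survey trends are conventionally quoted.
    """
    m0 = index.mean_for(year0)
    m1 = index.mean_for(year1)
    if m0 == 0:
        raise ZeroDivisionError("baseline year has zero index")
    total = 100.0 * (m0 - m1) / m0
    per_year = total / (year1 - year0)
    return total, per_year


def fit_report(
    samples: PosteriorSamples,
    data: FitData,
    rng_seed: int = 0,
    rhat_threshold: float = 1.1,
) -> dict:
    """Consolidated fit report, fully regenerable from the saved draws.

    Contains effect reports (mean, 95% CRI, direction probabilities)
    for every scalar parameter, the convergence table with a list of
    parameters at or above the R-hat threshold, the Bayesian p-value,
    the natural-unit threshold summary when standardization statistics
    are available, and residual-vs-predicted pairs (observed count
    against posterior-mean expected count per route-year).
    """
    effects = {}
    for name in samples.parameter_names:
        d = samples.pooled(name)
        effects[name] = EffectReport(
            parameter=name,
            mean=float(np.mean(d)),
            lower95=float(np.quantile(d, 0.025)),
            upper95=float(np.quantile(d, 0.975)),
            pr_positive=float(np.mean(d > 0)),
            pr_negative=float(np.mean(d < 0)),
        )

    rhat = {}
    not_converged = []
    if samples.n_chains > 1:
        for name in samples.parameter_names:
            rh = gelman_rubin(samples, name)
            rhat[name] = rh
            if rh >= rhat_threshold:
                not_converged.append(name)

    p_value = bayesian_p_value(samples, data, rng=rng_seed)

    eps_all = _pooled_eps(samples)
    n_pool = len(samples.pooled("r"))
    idx = np.unique(np.linspace(0, n_pool - 1, min(400, n_pool)).astype(int))
    mu_mean = np.zeros(data.n_cells)
    for d in idx:
        mu_mean += _draw_mu(samples, data, d, eps_all[d] if eps_all is not None else None)
    mu_mean /= len(idx)
    y_obs = data.y.mean(axis=1) if data.y.ndim == 2 else data.y.astype(float)
    residual_pairs = pd.DataFrame(
        {"observed": y_obs, "predicted": mu_mean, "residual": y_obs - mu_mean}
    )

    report = {
        "effects": effects,
        "rhat": rhat,
        "not_converged": not_converged,
        "bayesian_p_value": p_value,
        "residual_pairs": residual_pairs,
    }
    stds = samples.meta.get("standardizers", {})
    if "hinge_natural" in stds:
        report["threshold_natural"] = threshold_summary(samples, stds["hinge_natural"])
    return report


def effects_to_frame(effects: dict) -> pd.DataFrame:
    """Effect reports as a flat table (parameter, mean, CRI, directions)."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "mean": e.mean,
                "lower95": e.lower95,
                "upper95": e.upper95,
                "pr_positive": e.pr_positive,
                "pr_negative": e.pr_negative,
            }
            for e in effects.values()
        ]
    )
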