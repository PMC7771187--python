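"""Likelihood kernels for the change-point abundance model.

Two observation designs share the same latent process.  The log mean
abundance for route-year (i, t) is

    z = beta0 + X @ beta_weather + (beta5 + delta * 1[x >= phi]) * (x - phi) + eps

with X the standardized weather covariates and x the standardized hinge
covariate (percent grassland or edge density).  Latent abundance is
negative binomial with size ``r`` and success probability
``s = r / (r + mu)``, ``mu = exp(z)``, so that ``mu = r (1 - s) / s``
and the variance is ``mu + mu**2 / r``.

* Direct (single-visit) design: the observed count itself is the
  negative binomial draw.
* Lek (repeated-visit) design: each visit's count is a binomial
  thinning ``y_j ~ Binomial(N, p)`` of the latent abundance; the
  likelihood here marginalizes N by truncated summation.

All likelihoods are computed in log space with log-sum-exp for the
marginalization.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .params import ThresholdModelParams

__all__ = [
    "linear_predictor",
    "nb_success",
    "nb_logpmf",
    "nb_upper_bound",
    "loglik_direct",
    "loglik_lek_marginal",
]


def linear_predictor(
    params: ThresholdModelParams,
    weather_x: np.ndarray,
    hinge_x: np.ndarray,
    epsilon: np.ndarray | float | None = None,
) -> np.ndarray:
    """Log mean abundance z for each route-year.

    Parameters
    ----------
    weather_x
        Array of shape (n, 4): standardized PDSI, PCP, TMAX, TMIN.
    hinge_x
        Array of shape (n,): standardized hinge covariate.
    epsilon
        Route-year random intercepts; defaults to ``params.epsilon`` or 0.

    The indicator is 1 exactly when ``hinge_x - phi >= 0`` (ties fall on
    the post-threshold side), and the hinge term
    ``(beta5 + delta * I) * (hinge_x - phi)`` is continuous at the
    threshold for every delta.
    """
    weather_x = np.atleast_2d(np.asarray(weather_x, dtype=float))
    hinge_x = np.asarray(hinge_x, dtype=float)
    if epsilon is None:
        epsilon = params.epsilon if params.epsilon is not None else 0.0
    diff = hinge_x - params.phi
    slope = params.beta5 + params.delta * (diff >= 0)
    return params.beta0 + weather_x @ params.beta_weather + slope * diff + epsilon


def nb_success(mu, r):
    """Success probability s = r / (r + mu) of the negative binomial.

    Inverts the mean relation mu = r (1 - s) / s; s is in (0, 1] with
    s = 1 exactly when mu = 0.
    """
    mu = np.asarray(mu, dtype=float)
    if not np.all(r > 0):
        raise ValueError("overdispersion r must be > 0")
    if np.any(mu < 0):
        raise ValueError("mean mu must be >= 0")
    return r / (r + mu)


def nb_logpmf(y, mu, r):
    """Negative binomial log mass at counts y, parameterized by mean and size."""
    return stats.nbinom.logpmf(y, r, nb_success(mu, r))


def nb_upper_bound(mu, r, tail: float = 1e-10) -> int:
    """Smallest N beyond which the NegBin(mu, r) tail mass is below ``tail``."""
    s = nb_success(np.asarray(mu, dtype=float), r)
    return int(np.max(stats.nbinom.isf(tail, r, s))) + 1


def _z(params, weather_x, hinge_x, epsilon):
    return linear_predictor(params, weather_x, hinge_x, epsilon)


def loglik_direct(
    y: np.ndarray,
    params: ThresholdModelParams,
    weather_x: np.ndarray,
    hinge_x: np.ndarray,
    epsilon: np.ndarray | float | None = None,
) -> float:
    """Log-likelihood of single-visit counts under the NegBin observation model.

    Missing observations are encoded by excluding them from ``y`` (the
    function is a plain sum over the route-years supplied).
    """
    y = np.asarray(y)
    if y.size == 0:
        return 0.0
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    mu = np.exp(_z(params, weather_x, hinge_x, epsilon))
    return float(np.sum(nb_logpmf(y, mu, params.r)))


def loglik_lek_marginal(
    y_visits: np.ndarray,
    params: ThresholdModelParams,
    weather_x: np.ndarray,
    hinge_x: np.ndarray,
    epsilon: np.ndarray | float | None = None,
    n_max: int | None = None,
    tail: float = 1e-10,
) -> float:
    """Log-likelihood of repeated lek counts with latent abundance summed out.

    For each route-year with visit counts (y_1, ..., y_J),

        L = sum_{N = max_j y_j}^{n_max} NegBin(N | r, s) prod_j Binom(y_j | N, p)

    evaluated in log space.  ``n_max`` defaults to the point where the
    NegBin upper tail falls below ``tail`` (so the truncation error is
    negligible); supplying a smaller ``n_max`` than the largest observed
    count is an error.
    """
    y_visits = np.atleast_2d(np.asarray(y_visits))
    if y_visits.size == 0:
        return 0.0
    if np.any(y_visits < 0):
        raise ValueError("counts must be nonnegative")
    weather_x = np.atleast_2d(np.asarray(weather_x, dtype=float))
    hinge_x = np.atleast_1d(np.asarray(hinge_x, dtype=float))
    mu = np.exp(_z(params, weather_x, hinge_x, epsilon))
    mu = np.broadcast_to(np.atleast_1d(mu), (y_visits.shape[0],))
    r, p = params.r, params.p
    y_max = int(y_visits.max())
    if n_max is None:
        n_max = max(nb_upper_bound(mu, r, tail), y_max)
    if n_max < y_max:
        raise ValueError(f"n_max={n_max} below the largest observed count {y_max}")

    ns = np.arange(0, n_max + 1)
    total = 0.0
    s = nb_success(mu, r)
    for i in range(y_visits.shape[0]):
        yi = y_visits[i]
        lo = int(yi.max())
        grid = ns[lo:]
        log_nb = stats.nbinom.logpmf(grid, r, s[i])
        log_bin = np.zeros_like(log_nb)
        for yj in yi:
            log_bin += stats.binom.logpmf(yj, grid, p)
        total += logsumexp(log_nb + log_bin)
    return float(total)
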