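"""Posterior sampling for the change-point abundance model.

The sampler is an adaptive Metropolis-within-Gibbs scheme over the
marginalized likelihood: scalar parameters take Gaussian random-walk
proposals whose step sizes adapt toward a 0.44 acceptance rate during
burn-in only (so the post-burn-in chain is a valid fixed-kernel Markov
chain), and the route-year random intercepts are updated jointly with
independent per-cell accept/reject decisions, which is valid because
each intercept enters exactly one route-year's likelihood term.

For the repeated-visit (lek) design the latent abundances N are summed
out by default (truncated summation over a shared N grid with cached
combinatorial terms); a latent-N sampler — explicit discrete
Metropolis updates for each N plus a conjugate Beta draw for the
detection probability — is retained as a cross-validation of the
marginalized implementation.

Priors follow the hierarchical specification: Normal(0, 10) on the
intercept, the weather slopes, the pre-threshold slope and the
intensification coefficient; Uniform(l, u) on the threshold, with l, u
the standardized hinge covariate's observed extremes; Gamma(1, 1) on
the overdispersion; Uniform(0, 1) on detection; and random intercepts
eps ~ Normal(0, sigma) with sigma ~ HalfNormal(15) (or fixed, the
literal fixed-scale reading).  A ``scale_interpretation`` switch makes
the Normal scales readable as sd, variance or precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import math

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .params import ModelDesign, ThresholdModelParams
from .covariates import Standardizer

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "FitData",
    "PosteriorSamples",
    "sample_posterior",
    "gelman_rubin",
    "predict_missing",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PriorConfig:
    """Prior scales and shapes.

    ``scale_interpretation`` controls how the Normal scale numbers are
    read: ``"sd"`` (default; Normal(0, 10) means standard deviation 10),
    ``"variance"``, or ``"precision"``.  ``sigma_fixed`` fixes the
    random-intercept scale at a constant instead of giving it a
    half-normal hyperprior.
    """

    beta_scale: float = 10.0
    delta_scale: float = 10.0
    eps_scale: float = 15.0
    r_shape: float = 1.0
    r_rate: float = 1.0
    phi_bounds: tuple | None = None  # (l, u); standardized hinge min/max if None
    scale_interpretation: str = "sd"
    sigma_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.scale_interpretation not in ("sd", "variance", "precision"):
            raise ValueError(f"unknown scale interpretation {self.scale_interpretation!r}")
        for name in ("beta_scale", "delta_scale", "eps_scale", "r_shape", "r_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.phi_bounds is not None and not self.phi_bounds[0] < self.phi_bounds[1]:
            raise ValueError("phi bounds must satisfy l < u")

    def effective_sd(self, scale: float) -> float:
        if self.scale_interpretation == "sd":
            return scale
        if self.scale_interpretation == "variance":
            return float(np.sqrt(scale))
        return 1.0 / float(np.sqrt(scale))


@dataclass
class McmcConfig:
    """Chain protocol.  Desk-scale defaults; ``paper_protocol`` gives the
    long-run settings (200,000 burn-in, thin 5, 10,000 saved, 3 chains)."""

    n_chains: int = 3
    burn_in: int = 2000
    n_saved: int = 2000
    thin: int = 1
    seed: int = 0
    latent_n: str = "marginalized"  # or "sampled" (lek design only)
    adapt: bool = True
    store_eps: bool = True
    grid_cap: int = 4000
    max_init_attempts: int = 20

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.n_saved, self.thin) < 1:
            raise ValueError("all chain counts must be >= 1")
        if self.latent_n not in ("marginalized", "sampled"):
            raise ValueError(f"unknown latent_n handling {self.latent_n!r}")

    @classmethod
    def paper_protocol(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=3, burn_in=200_000, n_saved=10_000, thin=5, seed=seed)


# ---------------------------------------------------------------------------
# data container


@dataclass
class FitData:
    """Design matrices for one model fit.

    ``y`` has shape (n,) for the direct design or (n, J) for the lek
    design.  ``cells`` indexes the observed route-years; the
    ``missing_*`` fields carry covariates of unsurveyed route-years for
    posterior prediction.
    """

    design: ModelDesign
    y: np.ndarray
    weather_x: np.ndarray
    hinge_x: np.ndarray
    cells: pd.DataFrame
    standardizers: dict = field(default_factory=dict)
    missing_weather_x: np.ndarray | None = None
    missing_hinge_x: np.ndarray | None = None
    missing_cells: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.weather_x = np.asarray(self.weather_x, dtype=float)
        self.hinge_x = np.asarray(self.hinge_x, dtype=float)
        if np.any(self.y < 0):
            raise ValueError("counts must be nonnegative")
        if self.design.observation == "lek" and self.y.ndim != 2:
            raise ValueError("lek design requires repeated-visit counts (n, J)")
        if self.design.observation == "lek" and self.y.shape[1] < 2:
            raise ValueError("lek design needs >= 2 visits for detection identifiability")

    @property
    def n_cells(self) -> int:
        return len(self.hinge_x)

    @classmethod
    def from_tables(
        cls,
        counts: pd.DataFrame,
        covariates: pd.DataFrame,
        design: ModelDesign,
        standardizers: dict | None = None,
    ) -> "FitData":
        """Assemble fit data from the counts table and a built covariate table.

        Covariate-complete route-years without counts become prediction
        cells; covariate-incomplete route-years are excluded (they are
        flagged in the covariate table's ``missing`` column).
        """
        xcols = ["pdsi_summer_std", "pcp_winter_std", "tmax_summer_std", "tmin_winter_std"]
        cov = covariates[~covariates["missing"]].sort_values(["route_id", "year"])
        key = ["route_id", "year"]

        if design.observation == "lek":
            wide = counts.pivot_table(index=key, columns="visit", values="count", aggfunc="first")
            wide = wide.dropna().astype(int)
            obs = cov.merge(wide.reset_index(), on=key, how="inner")
            visit_cols = [c for c in obs.columns if isinstance(c, (int, np.integer))]
            y = obs[sorted(visit_cols)].to_numpy(dtype=int)
        else:
            tall = counts.groupby(key, as_index=False)["count"].first()
            obs = cov.merge(tall, on=key, how="inner")
            y = obs["count"].to_numpy(dtype=int)

        merged_keys = set(map(tuple, obs[key].to_numpy()))
        miss = cov[~cov.apply(lambda row: (row["route_id"], row["year"]) in merged_keys, axis=1)]
        return cls(
            design=design,
            y=y,
            weather_x=obs[xcols].to_numpy(),
            hinge_x=obs["hinge_natural_std"].to_numpy(),
            cells=obs[key + ["climate_region"]].reset_index(drop=True),
            standardizers=standardizers or {},
            missing_weather_x=miss[xcols].to_numpy() if len(miss) else None,
            missing_hinge_x=miss["hinge_natural_std"].to_numpy() if len(miss) else None,
            missing_cells=miss[key].reset_index(drop=True) if len(miss) else None,
        )

    @classmethod
    def from_dataset(cls, dataset, design: ModelDesign) -> "FitData":
        """Build fit data from a :class:`~thresholdnmix.simulate.SyntheticDataset`.

        Uses the same covariate table and standardization the simulator
        produced — the round trip involves no special-casing.
        """
        return cls.from_tables(
            dataset.counts, dataset.covariates, design, standardizers=dataset.standardizers
        )


# ---------------------------------------------------------------------------
# likelihood kernels (cached, vectorized over route-year cells)


class _DirectKernel:
    """Per-cell NegBin log-likelihood with gammaln terms cached per r."""

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.n_cells = len(y)
        self._gly1 = gammaln(self.y + 1.0)
        self._r = None

    def cell_loglik(self, z: np.ndarray, r: float, p: float | None = None):
        if self._r != r:
            self._glyr = gammaln(self.y + r) - gammaln(r)
            self._r = r
        mu = np.exp(z)
        log_rmu = np.log(r + mu)
        log_s = np.log(r) - log_rmu
        log_1ms = z - log_rmu
        return self._glyr - self._gly1 + r * log_s + self.y * log_1ms


@njit(cache=True)
def _lek_rows(logC, gl_r, lo, hi, c0, c1, buf):
    """Per-row truncated log-sum-exp of logC[i,N] + gl_r[N] + c1[i]*N, plus c0[i].

    Two passes per row: locate the maximum, then exponentiate only the
    terms within 45 log units of it (the rest are below double-precision
    resolution of the sum).
    """
    n = logC.shape[0]
    out = np.empty(n)
    for i in range(n):
        m = -1.0e308
        for N in range(lo[i], hi[i] + 1):
            t = logC[i, N] + gl_r[N] + c1[i] * N
            buf[N] = t
            if t > m:
                m = t
        acc = 0.0
        thr = m - 45.0
        for N in range(lo[i], hi[i] + 1):
            if buf[N] > thr:
                acc += math.exp(buf[N] - m)
        out[i] = c0[i] + m + math.log(acc)
    return out


class _LekKernel:
    """Marginalized lek likelihood over a truncated latent-N grid.

    The binomial-coefficient block is cached once; each evaluation is a
    per-cell log-sum-exp over N from the largest visit count up to
    ``mu + (6 + 24/sqrt(r)) * sd + 30`` (NegBin tail mass below 1e-9
    there, checked against the exact quantile across the r, mu range).
    Proposals whose implied means would need a grid beyond ``grid_cap``
    are reported as impossible (None), which the sampler treats as a
    rejection; with counts in the survey range such proposals have
    astronomically small likelihood anyway.
    """

    def __init__(self, y_visits: np.ndarray, grid_cap: int = 4000):
        self.y = np.asarray(y_visits, dtype=int)
        self.n_cells, self.J = self.y.shape
        self.ymax = self.y.max(axis=1).astype(np.int64)
        self.sumy = self.y.sum(axis=1).astype(float)
        self.grid_cap = int(grid_cap)
        self._T = -1
        self._d_cache = []
        self._ensure_grid(max(2 * int(self.ymax.max()) + 50, 64))

    def _ensure_grid(self, T: int) -> None:
        if T <= self._T:
            return
        T = min(max(int(T), int(1.5 * self._T)), self.grid_cap)
        self._T = T
        ns = np.arange(T + 1)
        gl_n1 = gammaln(ns + 1.0)
        logC = np.zeros((self.n_cells, T + 1))
        for j in range(self.J):
            yj = self.y[:, j][:, None].astype(float)
            diff = ns[None, :] - yj
            with np.errstate(invalid="ignore"):
                term = gl_n1[None, :] - gammaln(yj + 1.0) - gammaln(diff + 1.0)
            logC += np.where(diff >= 0, term, -np.inf)
        self._logC = logC
        self._gl_n1 = gl_n1
        self._buf = np.empty(T + 1)
        self._d_cache = []

    def _gl_r_vec(self, r: float) -> np.ndarray:
        # two-slot cache: the current r and one proposal coexist, so a
        # rejected overdispersion move does not evict the current vector
        key = (r, self._T)
        for k, v in self._d_cache:
            if k == key:
                return v
        ns = np.arange(self._T + 1.0)
        vec = gammaln(ns + r) - gammaln(r) - self._gl_n1
        self._d_cache = [(key, vec)] + self._d_cache[:1]
        return vec

    def cell_loglik(self, z: np.ndarray, r: float, p: float):
        z = np.minimum(z, 60.0)
        mu = np.exp(z)
        sd = np.sqrt(mu + mu * mu / r)
        bound = mu + (6.0 + 24.0 / np.sqrt(r)) * sd + 30.0
        needed = int(bound.max()) + 1
        if needed > self.grid_cap:
            return None
        self._ensure_grid(needed)
        gl_r = self._gl_r_vec(r)
        log_rmu = np.log(r + mu)
        c0 = r * (np.log(r) - log_rmu) + self.sumy * (np.log(p) - np.log1p(-p))
        c1 = (z - log_rmu) + self.J * np.log1p(-p)
        hi = np.maximum(np.minimum(bound.astype(np.int64), self._T), self.ymax)
        return _lek_rows(self._logC, gl_r, self.ymax, hi, c0, c1, self._buf)


class _LekLatentKernel:
    """Lek likelihood conditional on explicit latent abundances N."""

    def __init__(self, y_visits: np.ndarray):
        self.y = np.asarray(y_visits, dtype=int)
        self.n_cells, self.J = self.y.shape
        self.ymax = self.y.max(axis=1)
        self.sumy = self.y.sum(axis=1).astype(float)
        self._gl_y = gammaln(self.y + 1.0).sum(axis=1)

    def nb_part(self, N: np.ndarray, z: np.ndarray, r: float):
        mu = np.exp(z)
        log_rmu = np.log(r + mu)
        return (
            gammaln(N + r)
            - gammaln(r)
            - gammaln(N + 1.0)
            + r * (np.log(r) - log_rmu)
            + N * (z - log_rmu)
        )

    def binom_part(self, N: np.ndarray, p: float):
        Nf = N.astype(float)
        diff = self.J * gammaln(Nf + 1.0) - self._gl_y - gammaln(
            Nf[:, None] - self.y + 1.0
        ).sum(axis=1)
        out = diff + self.sumy * np.log(p) + (self.J * Nf - self.sumy) * np.log1p(-p)
        return np.where(N >= self.ymax, out, -np.inf)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Draws per chain per parameter plus provenance metadata.

    ``draws[name]`` has shape (n_chains, n_saved) for scalars and
    (n_chains, n_saved, n_cells) for the random intercepts ``eps``.
    """

    draws: dict
    meta: dict = field(default_factory=dict)

    @property
    def parameter_names(self):
        return [k for k in self.draws if self.draws[k].ndim == 2]

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def pooled(self, parameter: str) -> np.ndarray:
        """All chains' post-burn-in draws concatenated."""
        if parameter not in self.draws:
            raise KeyError(f"unknown parameter {parameter!r}")
        d = self.draws[parameter]
        return d.reshape(-1, *d.shape[2:])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.parameter_names:
            d = self.pooled(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(d)),
                    "sd": float(np.std(d, ddof=1)),
                    "q2.5": float(np.quantile(d, 0.025)),
                    "q50": float(np.quantile(d, 0.5)),
                    "q97.5": float(np.quantile(d, 0.975)),
                    "rhat": gelman_rubin(self, name) if self.n_chains > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        """One row per draw: chain, iteration, scalar parameter columns."""
        names = self.parameter_names
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame({n: self.draws[n][c] for n in names})
            df.insert(0, "iteration", np.arange(len(df)))
            df.insert(0, "chain", c)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def save_summary(self, path: str | Path) -> None:
        summ = self.summary().set_index("parameter")
        payload = {p: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                   for p, row in summ.iterrows()}
        Path(path).write_text(json.dumps(payload, indent=2))


def gelman_rubin(samples, parameter: str) -> float:
    """Potential scale reduction factor from between/within-chain variances.

    Chains are flagged non-converged when the statistic is >= 1.1.
    Requires at least two chains of at least ten draws.
    """
    if isinstance(samples, PosteriorSamples):
        chains = samples.draws[parameter]
    else:
        chains = np.asarray(samples[parameter] if isinstance(samples, dict) else samples)
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    m, n = chains.shape
    if n < 10:
        raise ValueError("Gelman-Rubin needs >= 10 draws per chain")
    chain_means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + (1 + 1 / m) * B_over_n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# the sampler


_SCALAR_ORDER = [
    "beta0", "beta1", "beta2", "beta3", "beta4", "beta5",
    "delta", "phi", "log_r", "logit_p", "log_sigma",
]


def _hinge_base(state, weather_x, hinge_x):
    diff = hinge_x - state["phi"]
    slope = state["beta5"] + state["delta"] * (diff >= 0)
    bw = np.array([state["beta1"], state["beta2"], state["beta3"], state["beta4"]])
    return state["beta0"] + weather_x @ bw + slope * diff


def _scalar_log_prior(name, value, priors: PriorConfig, phi_bounds):
    if name in ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5"):
        sd = priors.effective_sd(priors.beta_scale)
        return -0.5 * (value / sd) ** 2
    if name == "delta":
        sd = priors.effective_sd(priors.delta_scale)
        return -0.5 * (value / sd) ** 2
    if name == "phi":
        l, u = phi_bounds
        return 0.0 if l <= value <= u else -np.inf
    if name == "log_r":
        r = np.exp(value)
        return priors.r_shape * value - priors.r_rate * r  # Gamma prior + log Jacobian
    if name == "logit_p":
        # Uniform(0,1) prior on p; logistic Jacobian
        return -2.0 * np.logaddexp(0.0, -abs(value)) - abs(value)
    if name == "log_sigma":
        sigma = np.exp(value)
        sc = priors.effective_sd(priors.eps_scale)
        return -0.5 * (sigma / sc) ** 2 + value  # HalfNormal + log Jacobian
    raise KeyError(name)


def _eps_log_prior(eps, sigma):
    if sigma <= 0:
        return -np.inf if np.any(eps != 0) else 0.0
    return float(-0.5 * np.sum((eps / sigma) ** 2) - len(eps) * np.log(sigma))


def _run_chain(data: FitData, priors, cfg: McmcConfig, phi_bounds, rng, likelihood_off):
    lek = data.design.observation == "lek"
    latent = lek and cfg.latent_n == "sampled"
    n = data.n_cells

    if latent:
        kern = _LekLatentKernel(data.y)
    elif lek:
        kern = _LekKernel(data.y, grid_cap=cfg.grid_cap)
    else:
        kern = _DirectKernel(data.y)

    sigma_hier = priors.sigma_fixed is None
    active = ["beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "delta", "phi", "log_r"]
    if lek and not latent:
        active.append("logit_p")
    if sigma_hier:
        active.append("log_sigma")

    def initial_state(attempt):
        st = {k: 0.0 for k in _SCALAR_ORDER}
        st["phi"] = float(np.median(data.hinge_x))
        st["log_r"] = 0.0
        st["logit_p"] = 0.0
        st["log_sigma"] = np.log(0.5) if sigma_hier else np.log(max(priors.sigma_fixed, 1e-12))
        if attempt > 0:  # jittered re-initialization
            for k in active:
                st[k] += 0.3 * rng.normal()
            st["phi"] = float(np.clip(st["phi"], *phi_bounds))
        return st

    def cell_ll(z, st):
        if likelihood_off:
            return np.zeros(n)
        r = np.exp(st["log_r"])
        if latent:
            return kern.nb_part(state_N, z, r)
        if lek:
            p = 1.0 / (1.0 + np.exp(-st["logit_p"]))
            return kern.cell_loglik(z, r, p)
        return kern.cell_loglik(z, r)

    # --- initialization with bounded retries on non-finite likelihood
    state = None
    for attempt in range(cfg.max_init_attempts):
        cand = initial_state(attempt)
        eps = np.zeros(n)
        if latent:
            state_N = np.maximum(kern.ymax, 1).astype(int).copy()
        base = _hinge_base(cand, data.weather_x, data.hinge_x)
        ll = cell_ll(base + eps, cand)
        if ll is not None and np.all(np.isfinite(ll)):
            state = cand
            break
    if state is None:
        raise RuntimeError("could not find a finite-likelihood initialization")

    sigma = np.exp(state["log_sigma"]) if sigma_hier else priors.sigma_fixed
    steps = {k: 0.1 for k in active}
    steps["phi"] = 0.1 * (phi_bounds[1] - phi_bounds[0])
    eps_step = 0.2
    n_step = 3  # latent-N proposal half-width
    acc = {k: 0 for k in active}
    eps_acc = 0.0
    batch = max(cfg.burn_in // 40, 10)

    n_iter = cfg.burn_in + cfg.n_saved * cfg.thin
    saved = {k: np.empty(cfg.n_saved) for k in
             ["beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "delta", "phi", "r", "sigma"]
             + (["p"] if lek else [])}
    eps_saved = np.empty((cfg.n_saved, n), dtype=np.float32) if cfg.store_eps else None
    save_idx = 0

    total_ll = float(np.sum(ll))

    def scalar_logp(name, value):
        return _scalar_log_prior(name, value, priors, phi_bounds)

    for it in range(n_iter):
        # -- scalar global parameters, component-wise random walk
        for name in active:
            cur = state[name]
            prop = cur + steps[name] * rng.normal()
            lp_cur = scalar_logp(name, cur)
            lp_prop = scalar_logp(name, prop)
            if not np.isfinite(lp_prop):
                continue
            if name == "log_sigma":
                # sigma only touches the eps prior, not the likelihood;
                # repeat the cheap update to help the sigma/r trade-off mix
                for _ in range(3):
                    prop = state[name] + steps[name] * rng.normal()
                    lp_cur = scalar_logp(name, state[name])
                    lp_prop = scalar_logp(name, prop)
                    extra = _eps_log_prior(eps, np.exp(prop)) - _eps_log_prior(eps, sigma)
                    if np.log(rng.random()) < lp_prop - lp_cur + extra:
                        state[name] = prop
                        sigma = np.exp(prop)
                        acc[name] += 1.0 / 3.0
                continue
            trial = dict(state)
            trial[name] = prop
            if likelihood_off or name in ("log_r", "logit_p"):
                new_base = base
            else:
                new_base = _hinge_base(trial, data.weather_x, data.hinge_x)
            new_ll = ll if likelihood_off else cell_ll(new_base + eps, trial)
            if new_ll is None or not np.all(np.isfinite(new_ll)):
                continue
            new_total = float(np.sum(new_ll))
            if np.log(rng.random()) < (lp_prop + new_total) - (lp_cur + total_ll):
                state[name] = prop
                base = new_base
                ll = new_ll
                total_ll = new_total
                acc[name] += 1

        # -- random intercepts: independent per-cell Metropolis
        if sigma > 0 or likelihood_off:
            eps_prop = eps + eps_step * rng.normal(size=n)
            if likelihood_off and not sigma > 0:
                pass
            else:
                ll_prop = ll if likelihood_off else cell_ll(base + eps_prop, state)
                if ll_prop is not None:
                    with np.errstate(invalid="ignore"):
                        log_alpha = (
                            ll_prop - ll
                            - 0.5 * (eps_prop**2 - eps**2) / sigma**2
                        )
                    u = rng.random(size=n)
                    take = np.log(u) < log_alpha
                    take &= np.isfinite(ll_prop)
                    eps = np.where(take, eps_prop, eps)
                    ll = np.where(take, ll_prop, ll)
                    total_ll = float(np.sum(ll))
                    eps_acc += float(np.mean(take))

        # -- latent-N path: discrete N updates and conjugate p draw
        if latent:
            p_cur = rng.beta(1.0 + kern.sumy.sum(),
                             1.0 + float(np.sum(kern.J * state_N - kern.sumy)))
            p_cur = min(max(p_cur, 1e-12), 1 - 1e-12)
            state["logit_p"] = float(np.log(p_cur) - np.log1p(-p_cur))
            shift = rng.integers(-n_step, n_step + 1, size=n)
            N_prop = np.maximum(state_N + shift, 0)
            r = np.exp(state["log_r"])
            z = base + eps
            cur_part = kern.nb_part(state_N, z, r) + kern.binom_part(state_N, p_cur)
            prop_part = kern.nb_part(N_prop, z, r) + kern.binom_part(N_prop, p_cur)
            with np.errstate(invalid="ignore"):
                take = np.log(rng.random(size=n)) < (prop_part - cur_part)
            take &= np.isfinite(prop_part)
            state_N = np.where(take, N_prop, state_N)
            ll = kern.nb_part(state_N, z, r)
            total_ll = float(np.sum(ll))

        # -- step-size adaptation during burn-in only
        if cfg.adapt and it < cfg.burn_in and (it + 1) % batch == 0:
            gain = min(0.5, 2.0 / np.sqrt((it + 1) / batch))
            for name in active:
                rate = acc[name] / batch
                steps[name] *= np.exp(gain * (rate - 0.44))
                acc[name] = 0
            rate = eps_acc / batch
            eps_step *= np.exp(gain * (rate - 0.44))
            eps_acc = 0.0

        # -- save
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            for k in ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "delta", "phi"):
                saved[k][save_idx] = state[k]
            saved["r"][save_idx] = np.exp(state["log_r"])
            saved["sigma"][save_idx] = sigma
            if lek:
                saved["p"][save_idx] = 1.0 / (1.0 + np.exp(-state["logit_p"]))
            if eps_saved is not None:
                eps_saved[save_idx] = eps
            save_idx += 1

    diag = {"steps": steps, "eps_step": eps_step}
    return saved, eps_saved, diag


def sample_posterior(
    design: ModelDesign,
    data: FitData,
    priors: PriorConfig | None = None,
    config: McmcConfig | None = None,
    likelihood_off: bool = False,
) -> PosteriorSamples:
    """Draw posterior samples for all model parameters.

    ``likelihood_off`` replaces every likelihood term by zero, so the
    chain targets the prior — used to validate the sampler against the
    prior marginals.  Runs are reproducible: chain c uses the stream
    seeded with ``config.seed + c``.
    """
    priors = priors or PriorConfig()
    config = config or McmcConfig()
    if design.observation == "direct" and config.latent_n == "sampled":
        raise ValueError("latent-N sampling applies to the lek design only")

    if priors.phi_bounds is not None:
        phi_bounds = tuple(priors.phi_bounds)
    else:
        phi_bounds = (float(np.min(data.hinge_x)), float(np.max(data.hinge_x)))
    if not phi_bounds[0] < phi_bounds[1]:
        raise ValueError("degenerate hinge covariate: cannot bound the threshold")

    all_saved, all_eps, diags = [], [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        saved, eps_saved, diag = _run_chain(data, priors, config, phi_bounds, rng, likelihood_off)
        all_saved.append(saved)
        all_eps.append(eps_saved)
        diags.append(diag)

    draws = {
        k: np.stack([s[k] for s in all_saved]) for k in all_saved[0]
    }
    if config.store_eps and all_eps[0] is not None:
        draws["eps"] = np.stack(all_eps).astype(float)
    meta = {
        "design": design,
        "phi_bounds": phi_bounds,
        "priors": priors,
        "config": config,
        "standardizers": data.standardizers,
        "cells": data.cells,
        "diagnostics": diags,
        "likelihood_off": likelihood_off,
    }
    return PosteriorSamples(draws=draws, meta=meta)


def predict_missing(
    samples: PosteriorSamples,
    data: FitData,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Posterior-predictive abundance draws for unsurveyed route-years.

    For each saved posterior draw, a route-year abundance is generated
    from the latent process: a fresh random-intercept draw
    eps* ~ Normal(0, sigma), then N* ~ NegBin with that draw's
    parameters at the route-year's covariates.  Returns an array of
    shape (n_pooled_draws, n_missing) and the missing-cell index; the
    array is empty when nothing is missing.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if data.missing_hinge_x is None or len(data.missing_hinge_x) == 0:
        return np.zeros((0, 0)), pd.DataFrame(columns=["route_id", "year"])

    beta0 = samples.pooled("beta0")
    bw = np.stack([samples.pooled(f"beta{i}") for i in (1, 2, 3, 4)], axis=1)
    beta5 = samples.pooled("beta5")
    delta = samples.pooled("delta")
    phi = samples.pooled("phi")
    r = samples.pooled("r")
    sigma = samples.pooled("sigma")

    xw = data.missing_weather_x
    hx = data.missing_hinge_x
    n_draws, n_miss = len(beta0), len(hx)
    out = np.empty((n_draws, n_miss))
    for d in range(n_draws):
        diff = hx - phi[d]
        slope = beta5[d] + delta[d] * (diff >= 0)
        eps_star = rng.normal(0.0, sigma[d], size=n_miss) if sigma[d] > 0 else 0.0
        mu = np.exp(beta0[d] + xw @ bw[d] + slope * diff + eps_star)
        s = r[d] / (r[d] + mu)
        out[d] = rng.negative_binomial(r[d], s)
    return out, data.missing_cells.copy()
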