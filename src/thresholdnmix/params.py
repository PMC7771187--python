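"""Parameter containers for the change-point abundance model.

The model describes route-level counts of breeding game birds.  Latent
abundance N[i,t] on route i in year t follows a negative binomial whose
log-mean is a linear function of four standardized weather covariates
plus a continuous piecewise-linear ("hinge") effect of one landscape
covariate: the slope is ``beta5`` below the threshold ``phi`` and
``beta5 + delta`` above it.  Repeated-visit (lek) designs add a binomial
detection layer with probability ``p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

WEATHER_NAMES = ("pdsi_summer", "pcp_winter", "tmax_summer", "tmin_winter")


@dataclass
class ThresholdModelParams:
    """Full parameter set of the threshold abundance model.

    Parameters
    ----------
    beta0
        Intercept on the log scale.
    beta_weather
        Coefficients (standardized units) for summer drought index,
        winter precipitation, summer maximum temperature and winter
        minimum temperature, in that order.
    beta5
        Slope of the hinge covariate below the threshold.
    delta
        Intensification coefficient: the change in slope at the
        threshold, so the post-threshold slope is ``beta5 + delta``.
    phi
        Threshold location on the *standardized* hinge covariate.
    r
        Negative-binomial overdispersion (size) parameter, > 0.
    p
        Per-visit detection probability in (0, 1]; only meaningful for
        repeated-count (lek) designs.
    sigma
        Scale of the route-year random intercepts, >= 0.
    epsilon
        Optional realized route-year random intercepts.
    """

    beta0: float = 0.0
    beta_weather: np.ndarray = field(default_factory=lambda: np.zeros(4))
    beta5: float = 0.0
    delta: float = 0.0
    phi: float = 0.0
    r: float = 1.0
    p: float = 1.0
    sigma: float = 0.0
    epsilon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_weather = np.asarray(self.beta_weather, dtype=float)
        if self.beta_weather.shape != (4,):
            raise ValueError("beta_weather must have exactly 4 coefficients")
        if not self.r > 0:
            raise ValueError(f"overdispersion r must be > 0, got {self.r}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"detection p must be in (0, 1], got {self.p}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.epsilon is not None:
            self.epsilon = np.asarray(self.epsilon, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_weather"] = self.beta_weather.tolist()
        if self.epsilon is not None:
            d["epsilon"] = np.asarray(self.epsilon).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModelParams":
        d = dict(d)
        if d.get("epsilon") is not None:
            d["epsilon"] = np.asarray(d["epsilon"], dtype=float)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ModelDesign:
    """Observation design and hinge-covariate choice for one model fit.

    ``observation`` is ``"lek"`` for repeated within-season counts with a
    binomial detection layer, or ``"direct"`` for single-visit auditory
    counts modeled as negative binomial directly (no detection
    probability).  ``hinge`` names the landscape covariate carrying the
    change point (percent grassland or grassland edge density), and
    ``buffer`` labels the buffer radius the landscape metrics were
    computed in.
    """

    observation: str = "direct"
    hinge: str = "grass"
    buffer: str = "3km"

    OBSERVATIONS = ("lek", "direct")
    HINGES = ("grass", "ed")
    BUFFERS = ("3km", "5km", "10km")

    def __post_init__(self) -> None:
        if self.observation not in self.OBSERVATIONS:
            raise ValueError(f"unknown observation design {self.observation!r}")
        if self.hinge not in self.HINGES:
            raise ValueError(f"unknown hinge covariate {self.hinge!r}")
        if self.buffer not in self.BUFFERS:
            raise ValueError(f"unknown buffer label {self.buffer!r}")
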