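"""Weather and land-cover covariate construction.

Four weather covariates enter the abundance model, each built from
monthly climate-region series and standardized:

* summer drought: mean Palmer Drought Severity Index over June-August
  of the year *before* the survey (one-year lag);
* summer heat: highest monthly maximum temperature over the same lagged
  June-August window;
* winter cold: lowest monthly minimum temperature over the winter
  preceding the breeding season (December of year-1, January and
  February of the survey year);
* winter precipitation: mean of the three monthly totals over that same
  winter window.

Land-cover covariates (percent grassland, edge density) are constant
within a Conservation Reserve Program contract period and are paired to
survey years through the period table.

A missing month inside any window yields an explicit NaN covariate —
route-years are flagged, never silently imputed or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "summer_drought",
    "summer_tmax",
    "winter_tmin",
    "winter_precip",
    "assign_contract_period",
    "Standardizer",
    "build_covariate_table",
    "WEATHER_COLUMNS",
]

WEATHER_COLUMNS = ("pdsi", "tmax", "tmin", "pcp")
COVARIATE_NAMES = ("pdsi_summer", "pcp_winter", "tmax_summer", "tmin_winter")


def _window_values(weather: pd.DataFrame, region, months_years, column: str):
    """Monthly values for the (year, month) pairs given; NaN if any is absent."""
    sub = weather[weather["region"] == region]
    out = []
    for year, month in months_years:
        rows = sub[(sub["year"] == year) & (sub["month"] == month)]
        if len(rows) == 0 or pd.isna(rows[column].iloc[0]):
            return None
        out.append(float(rows[column].iloc[0]))
    return out


def summer_drought(weather: pd.DataFrame, region, year: int) -> float:
    """Mean June-August PDSI of the year before ``year`` (1-year lag)."""
    vals = _window_values(weather, region, [(year - 1, m) for m in (6, 7, 8)], "pdsi")
    return np.nan if vals is None else float(np.mean(vals))


def summer_tmax(weather: pd.DataFrame, region, year: int) -> float:
    """Highest monthly maximum temperature, June-August of the prior year."""
    vals = _window_values(weather, region, [(year - 1, m) for m in (6, 7, 8)], "tmax")
    return np.nan if vals is None else float(np.max(vals))


def winter_tmin(weather: pd.DataFrame, region, year: int) -> float:
    """Lowest monthly minimum temperature over the preceding winter.

    The window spans two calendar years: December of ``year - 1`` and
    January and February of ``year``.
    """
    window = [(year - 1, 12), (year, 1), (year, 2)]
    vals = _window_values(weather, region, window, "tmin")
    return np.nan if vals is None else float(np.min(vals))


def winter_precip(weather: pd.DataFrame, region, year: int) -> float:
    """Mean of the three monthly precipitation totals of the preceding winter."""
    window = [(year - 1, 12), (year, 1), (year, 2)]
    vals = _window_values(weather, region, window, "pcp")
    return np.nan if vals is None else float(np.mean(vals))


def assign_contract_period(year: int, periods) -> tuple[int, int]:
    """The unique contract period whose inclusive [start, end] contains ``year``.

    ``periods`` is an iterable of (start_year, end_year) pairs (extra
    trailing elements such as labels are ignored).  Raises when the year
    is not covered, naming the year.
    """
    for per in periods:
        start, end = int(per[0]), int(per[1])
        if start <= year <= end:
            return (start, end)
    raise ValueError(f"year {year} is not covered by any contract period")


@dataclass
class Standardizer:
    """Invertible z-scoring with sample (n-1) standard deviation.

    Statistics are computed once over all route-years entering a model
    and shared by the simulator, fitter and back-transformer, so the
    threshold's standardized location means the same thing everywhere.
    """

    mean: float = 0.0
    sd: float = 1.0

    @classmethod
    def fit(cls, values) -> "Standardizer":
        values = np.asarray(values, dtype=float)
        finite = values[np.isfinite(values)]
        if np.unique(finite).size < 2:
            raise ValueError("standardization needs at least 2 distinct finite values")
        sd = float(np.std(finite, ddof=1))
        if sd == 0:
            raise ValueError("cannot standardize a constant input (sd = 0)")
        return cls(mean=float(np.mean(finite)), sd=sd)

    def transform(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values):
        return np.asarray(values, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=float(d["mean"]), sd=float(d["sd"]))


def _weather_covariate_table(weather: pd.DataFrame) -> pd.DataFrame:
    """All four weather covariates for every (region, survey year) at once.

    Vectorized equivalent of the per-route-year window functions: the
    lagged June-August windows and the boundary-spanning
    December-February windows, with a window missing any month (or any
    value) yielding NaN.
    """
    w = weather.copy()

    def window(frame, col, how, expected=3):
        grp = frame.groupby(["region", "survey_year"])[col]
        agg = grp.agg(["size", "count", how])
        ok = (agg["size"] == expected) & (agg["count"] == expected)
        out = agg[how].where(ok)
        return out

    summer = w[w["month"].isin([6, 7, 8])].copy()
    summer["survey_year"] = summer["year"] + 1  # 1-year lag
    winter = w[w["month"].isin([12, 1, 2])].copy()
    winter["survey_year"] = np.where(winter["month"] == 12, winter["year"] + 1, winter["year"])

    parts = pd.DataFrame(
        {
            "pdsi_summer": window(summer, "pdsi", "mean"),
            "tmax_summer": window(summer, "tmax", "max"),
            "tmin_winter": window(winter, "tmin", "min"),
            "pcp_winter": window(winter, "pcp", "mean"),
        }
    ).reset_index()
    return parts.rename(columns={"region": "climate_region", "survey_year": "year"})


def build_covariate_table(
    cells: pd.DataFrame,
    weather: pd.DataFrame,
    landcover: pd.DataFrame,
    periods,
    hinge: str = "grass",
    standardizers: dict[str, Standardizer] | None = None,
) -> tuple[pd.DataFrame, dict[str, Standardizer]]:
    """Assemble natural- and standardized-unit covariates per route-year.

    Parameters
    ----------
    cells
        One row per route-year with columns ``route_id``, ``year`` and
        ``climate_region``.
    weather
        Monthly series with columns region, year, month, pdsi, tmax,
        tmin, pcp.
    landcover
        Per route-period values: route_id, period_start, period_end,
        grass_pct, edge_density.
    periods
        Contract-period table, list of (start, end) pairs.
    hinge
        ``"grass"`` or ``"ed"``: which landscape covariate carries the
        change point.
    standardizers
        Pre-fitted statistics to reuse (e.g. the simulator reusing the
        fitting pipeline's standardization); fitted from the data when
        omitted.

    Returns the covariate table (with a boolean ``missing`` flag for
    route-years lacking any covariate) and the standardizer per
    covariate.  Standardization statistics are computed over the
    complete route-years only.
    """
    if hinge not in ("grass", "ed"):
        raise ValueError(f"unknown hinge covariate {hinge!r}")
    hinge_col = "grass_pct" if hinge == "grass" else "edge_density"

    wtab = _weather_covariate_table(weather)
    tab = cells.merge(wtab, on=["climate_region", "year"], how="left")

    # contract-period pairing of land cover
    starts, ends, hvals = [], [], []
    lc = landcover.set_index(["route_id", "period_start", "period_end"])
    for _, row in tab.iterrows():
        start, end = assign_contract_period(int(row["year"]), periods)
        starts.append(start)
        ends.append(end)
        try:
            hvals.append(float(lc.loc[(row["route_id"], start, end), hinge_col]))
        except KeyError:
            hvals.append(np.nan)
    tab["period_start"] = starts
    tab["period_end"] = ends
    tab["hinge_natural"] = hvals
    tab["hinge_name"] = hinge

    natural_cols = list(COVARIATE_NAMES) + ["hinge_natural"]
    tab["missing"] = tab[natural_cols].isna().any(axis=1)

    complete = tab[~tab["missing"]]
    if standardizers is None:
        standardizers = {c: Standardizer.fit(complete[c]) for c in natural_cols}
    for c in natural_cols:
        tab[c + "_std"] = standardizers[c].transform(tab[c])
    return tab, standardizers
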