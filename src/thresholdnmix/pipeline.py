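"""Run configuration, input validation and end-to-end orchestration.

A run is fully described by a :class:`RunConfig` (loadable from YAML or
JSON): which observation design and hinge covariate to fit, at which
buffer scale, where the input tables live, and the prior/MCMC settings.
``run_pipeline`` executes covariate building, standardization, fitting,
diagnostics and reporting, writing a manifest with the config hash and
seeds so a rerun reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import build_covariate_table, WEATHER_COLUMNS
from .mcmc import FitData, McmcConfig, PriorConfig, sample_posterior
from .params import ModelDesign
from .posterior import abundance_index, effects_to_frame, fit_report

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_run_config"]

_DESIGN_LABELS = {"lek2": "lek", "direct1": "direct"}


@dataclass
class RunConfig:
    """Everything needed to reproduce one model fit."""

    species_design: str = "direct1"        # lek2 | direct1
    hinge: str = "grass"                   # grass | ed
    buffer: str = "3km"                    # 3km | 5km | 10km
    counts_path: str = "counts.csv"
    weather_path: str = "weather.csv"
    covariates_path: str = "covariates.csv"
    contract_periods: tuple = ((1996, 2005), (2006, 2014))
    seed: int = 0
    paper_protocol: bool = False
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species_design not in _DESIGN_LABELS:
            raise ValueError(
                f"species design must be one of {sorted(_DESIGN_LABELS)}, got {self.species_design!r}"
            )
        ModelDesign(_DESIGN_LABELS[self.species_design], self.hinge, self.buffer)  # validates

    def design(self) -> ModelDesign:
        return ModelDesign(_DESIGN_LABELS[self.species_design], self.hinge, self.buffer)

    def prior_config(self) -> PriorConfig:
        return PriorConfig(**self.priors)

    def mcmc_config(self) -> McmcConfig:
        if self.paper_protocol:
            base = McmcConfig.paper_protocol(seed=self.seed)
            return base
        kw = dict(self.mcmc)
        kw.setdefault("seed", self.seed)
        return McmcConfig(**kw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if "contract_periods" in data:
        data["contract_periods"] = tuple(tuple(p) for p in data["contract_periods"])
    return RunConfig(**data)


def validate_inputs(
    counts_path: str | Path | None = None,
    weather_path: str | Path | None = None,
    covariates_path: str | Path | None = None,
    contract_periods=None,
) -> list[str]:
    """Schema and referential-integrity checks; returns a failure list
    (empty for clean inputs)."""
    failures: list[str] = []

    counts = weather = covs = None
    if counts_path is not None:
        try:
            counts = pd.read_csv(counts_path)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            failures.append(f"counts: unreadable ({exc})")
    if weather_path is not None:
        try:
            weather = pd.read_csv(weather_path)
        except Exception as exc:  # noqa: BLE001
            failures.append(f"weather: unreadable ({exc})")
    if covariates_path is not None:
        try:
            covs = pd.read_csv(covariates_path)
        except Exception as exc:  # noqa: BLE001
            failures.append(f"covariates: unreadable ({exc})")

    if counts is not None:
        need = {"route_id", "year", "visit", "count", "climate_region"}
        missing_cols = need - set(counts.columns)
        if missing_cols:
            failures.append(f"counts: missing columns {sorted(missing_cols)}")
        else:
            dup = counts.duplicated(["route_id", "year", "visit"])
            for line in (np.flatnonzero(dup.to_numpy()) + 2):  # +2: header + 1-based
                failures.append(f"counts: duplicate (route, year, visit) row at line {line}")
            if (counts["count"] < 0).any():
                failures.append("counts: negative counts present")

    if weather is not None:
        need = {"region", "year", "month"} | set(WEATHER_COLUMNS)
        missing_cols = need - set(weather.columns)
        if missing_cols:
            failures.append(f"weather: missing columns {sorted(missing_cols)}")
        else:
            if not weather["month"].between(1, 12).all():
                failures.append("weather: months outside 1-12")
            if weather.duplicated(["region", "year", "month"]).any():
                failures.append("weather: duplicate (region, year, month) records")

    if counts is not None and weather is not None and not failures:
        regions = set(weather["region"].unique())
        bad = set(counts["climate_region"].unique()) - regions
        if bad:
            failures.append(f"counts: climate regions {sorted(bad)} absent from weather")
        # every needed window month present
        wkey = set(map(tuple, weather[["region", "year", "month"]].to_numpy()))
        for (region, year), _ in counts.groupby(["climate_region", "year"]):
            windows = [(year - 1, m) for m in (6, 7, 8)] + [(year - 1, 12), (year, 1), (year, 2)]
            for yy, mm in windows:
                if (region, yy, mm) not in wkey:
                    failures.append(
                        f"weather: region {region} missing {yy}-{mm:02d} needed for survey year {year}"
                    )

    if covs is not None:
        need = {"route_id", "period_start", "period_end", "grass_pct", "edge_density"}
        missing_cols = need - set(covs.columns)
        if missing_cols:
            failures.append(f"covariates: missing columns {sorted(missing_cols)}")

    if counts is not None and contract_periods is not None and "year" in counts.columns:
        covered = set()
        for a, b in contract_periods:
            covered.update(range(int(a), int(b) + 1))
        bad_years = sorted(set(counts["year"].unique()) - covered)
        if bad_years:
            failures.append(f"counts: years {bad_years} not covered by the contract-period table")

    return failures


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Covariate building -> standardization -> fit -> diagnostics -> reports.

    Writes draws.csv, summary.json, effects.csv, index.csv, report.json
    and a manifest.json recording the config hash and seed.  Any stage
    failure aborts with a stage-named error and marks the output
    directory invalid.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INVALID"
    marker.write_text("run in progress\n")

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    counts = stage("read-counts")(lambda: pd.read_csv(config.counts_path))
    weather = stage("read-weather")(lambda: pd.read_csv(config.weather_path))
    landcover = stage("read-covariates")(lambda: pd.read_csv(config.covariates_path))

    failures = validate_inputs(
        config.counts_path, config.weather_path, config.covariates_path, config.contract_periods
    )
    if failures:
        raise RuntimeError("pipeline stage 'validate' failed: " + "; ".join(failures[:5]))

    def build():
        cells = counts[["route_id", "year", "climate_region"]].drop_duplicates()
        # complete the route-year grid so unsurveyed years can be predicted
        routes = cells[["route_id", "climate_region"]].drop_duplicates()
        years = np.arange(counts["year"].min(), counts["year"].max() + 1)
        grid = routes.merge(pd.DataFrame({"year": years}), how="cross")
        return build_covariate_table(
            grid, weather, landcover, config.contract_periods, hinge=config.hinge
        )

    cov, standardizers = stage("build-covariates")(build)
    design = config.design()
    data = stage("assemble")(lambda: FitData.from_tables(counts, cov, design, standardizers))
    samples = stage("fit")(
        lambda: sample_posterior(design, data, config.prior_config(), config.mcmc_config())
    )

    def report():
        rep = fit_report(samples, data, rng_seed=config.seed)
        samples.to_csv(outdir / "draws.csv")
        samples.save_summary(outdir / "summary.json")
        effects_to_frame(rep["effects"]).to_csv(outdir / "effects.csv", index=False)
        idx = abundance_index(samples, data, rng=config.seed)
        idx.table.to_csv(outdir / "index.csv", index=False)
        payload = {
            "bayesian_p_value": rep["bayesian_p_value"],
            "rhat": rep["rhat"],
            "not_converged": rep["not_converged"],
        }
        if "threshold_natural" in rep:
            payload["threshold_natural"] = rep["threshold_natural"]
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
        return rep

    stage("report")(report)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "design": config.species_design,
        "hinge": config.hinge,
        "buffer": config.buffer,
        "n_cells": int(data.n_cells),
        "outputs": ["draws.csv", "summary.json", "effects.csv", "index.csv", "report.json"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    marker.unlink()
    return outdir
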