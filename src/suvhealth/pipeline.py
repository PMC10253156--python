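"""End-to-end pipeline: fleet -> profiles -> projections -> health -> reports.

Every output is a delimited text file regenerated from the stage outputs of
the same run (nothing is cached between runs), and a JSON manifest records
the seed, a hash of the configuration and the package version so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .fleet import DistanceAssumptions, build_segment_profiles, profiles_frame, read_fleet, write_fleet
from .health import (LifeTablePopulation, ValuationParams, life_years_gained,
                     sensitivity_grid, value_life_years)
from .nox import delta_series, fleet_annual_nox
from .regression import fit_co2_model, fit_nox_model, write_report
from .scenarios import SCENARIOS, CohortProfiles, SalesTrajectory
from .co2 import cumulative_table, valuation_table
from .synth import FleetGenConfig, PopulationGenConfig, generate_fleet, generate_population
from .turnover import calibrate_survival

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns the output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fleet = _stage("fleet")(
        lambda: read_fleet(config.fleet_path) if config.fleet_path
        else generate_fleet(FleetGenConfig(seed=config.seed)))()
    if config.fleet_path is None:
        paths["fleet"] = out / "fleet.csv"
        write_fleet(fleet, paths["fleet"])

    population = _stage("population")(
        lambda: LifeTablePopulation.from_file(config.population_path)
        if config.population_path
        else generate_population(PopulationGenConfig(seed=config.seed)))()

    distances = DistanceAssumptions()
    profiles = _stage("profiles")(build_segment_profiles)(fleet, distances)
    paths["segment_profiles"] = out / "segment_profiles.csv"
    profiles_frame(profiles).to_csv(paths["segment_profiles"], index=False)

    regs = _stage("regression")(lambda: {
        "co2": fit_co2_model(fleet),
        "nox_diesel": fit_nox_model(fleet, "diesel"),
        "nox_petrol": fit_nox_model(fleet, "petrol"),
    })()
    paths["regression"] = out / "regression.csv"
    write_report(regs, paths["regression"])

    calib = _stage("turnover")(calibrate_survival)()
    paths["survival"] = out / "survival_schedule.csv"
    calib.schedule.to_file(paths["survival"])

    cohort_profiles = CohortProfiles.from_records(fleet, distances)
    sales = SalesTrajectory(base_year_sales=cohort_profiles.total_registrations)
    grid = config.grid()
    limits = config.euro_limits()
    legacy = config.legacy()
    scen = {n: SCENARIOS[n] for n in config.scenarios}

    cum = _stage("co2")(cumulative_table)(
        cohort_profiles, calib.schedule, grid, sales,
        horizons=tuple(config.horizons), scenarios=scen)
    paths["cumulative_co2"] = out / "cumulative_co2.csv"
    cum.to_csv(paths["cumulative_co2"], index=False)
    paths["carbon_value"] = out / "carbon_value.csv"
    valuation_table(cum, config.carbon_prices).to_csv(paths["carbon_value"], index=False)

    years = range(2020, config.nox_years_until + 1)
    nox_rows = []
    deltas: dict[str, pd.Series] = {}
    for name, spec in scen.items():
        series = _stage("nox")(delta_series)(
            spec, years, cohort_profiles, calib.schedule, sales, legacy,
            limits, distances)
        deltas[name] = series
        for y in years:
            nox_rows.append({
                "scenario": name, "year": y,
                "fleet_nox_t": fleet_annual_nox(spec, y, cohort_profiles,
                                                calib.schedule, sales, legacy,
                                                limits, distances),
                "delta_no2_ug_m3": series[y],
            })
    paths["fleet_nox"] = out / "fleet_nox.csv"
    pd.DataFrame(nox_rows).to_csv(paths["fleet_nox"], index=False)

    health_rows = []
    ly_by_scenario: dict[str, float] = {}
    value_by_scenario: dict[str, float] = {}
    for name in scen:
        if name == "BAU":
            ly_by_scenario[name], value_by_scenario[name] = 0.0, 0.0
            continue
        total, by_year = _stage("health")(life_years_gained)(
            population, deltas[name], end_year=config.health_end_year)
        ly_by_scenario[name] = total
        value_by_scenario[name] = value_life_years(by_year, ValuationParams())
    ref = ly_by_scenario.get("Electrified")
    for name in scen:
        if name == "BAU":
            continue
        row = {"scenario": name,
               "life_years_gained_vs_bau": ly_by_scenario[name],
               "value_gbp": value_by_scenario[name]}
        if ref:
            row["pct_change_vs_electrified"] = 100.0 * (ly_by_scenario[name] / ref - 1.0)
            row["value_pct_change_vs_electrified"] = 100.0 * (
                value_by_scenario[name] / value_by_scenario["Electrified"] - 1.0)
        health_rows.append(row)
    paths["life_years"] = out / "life_years.csv"
    pd.DataFrame(health_rows, columns=[
        "scenario", "life_years_gained_vs_bau", "value_gbp",
        "pct_change_vs_electrified", "value_pct_change_vs_electrified",
    ]).to_csv(paths["life_years"], index=False)

    most_ambitious = ("ElectrifiedSmallSUV" if "ElectrifiedSmallSUV" in deltas
                      else max(deltas, key=lambda n: deltas[n].iloc[-1]))
    if most_ambitious != "BAU":
        grid_df = _stage("sensitivity")(sensitivity_grid)(
            population, deltas[most_ambitious], volys=config.volys,
            rates=config.discount_rates, coefficients=config.rr_coefficients,
            end_year=config.health_end_year)
        paths["sensitivity"] = out / "sensitivity.csv"
        grid_df.to_csv(paths["sensitivity"], index=False)

    manifest = {
        "package": "suvhealth",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
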