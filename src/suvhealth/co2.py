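"""Cumulative CO2(e) projection from post-2020 sales cohorts, with valuation.

Every cohort of new registrations emits, in each calendar year it remains in
service, its surviving count times a per-vehicle annual rate:
internal-combustion vehicles use the 2020 per-vehicle segment means (fuel
efficiency of new sales assumed constant), battery-electric vehicles use the
energy drawn for their annual distance times the grid carbon intensity of
that year.  Cohort attrition follows the stock-turnover survival schedule for
all drivetrains.  Cumulative totals sum cohort-by-year emissions from the
policy start through the horizon year inclusive, and are valued with marginal
abatement costs (GBP per tonne of CO2e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import (SCENARIOS, CohortProfiles, SalesTrajectory,
                        ScenarioSpec, compose_cohort, POLICY_START)
from .turnover import SurvivalSchedule

__all__ = [
    "GridIntensitySeries",
    "CARBON_PRICES",
    "bev_annual_co2",
    "bev_lifetime_co2",
    "cumulative_co2",
    "value_carbon",
    "cumulative_table",
    "valuation_table",
]

#: Marginal CO2e abatement values (GBP/tonne, 2020 prices): low/central/high.
CARBON_PRICES = {
    2035: {"low": 151.1, "central": 302.3, "high": 453.4},
    2050: {"low": 189.2, "central": 378.3, "high": 567.5},
}


@dataclass(frozen=True)
class GridIntensitySeries:
    """Mean annual grid carbon intensity (gCO2e/kWh) and BEV energy use.

    The default trajectory is a configurable piecewise-linear stand-in for a
    net-zero-consistent pathway: 180 g/kWh in 2020, falling to 30 by 2030 and
    2 by 2035 (electricity is essentially decarbonised before the combustion
    ban completes), then 1 by 2050; held flat outside the range.  BEV
    efficiency defaults to 6.5 km/kWh at 15,180 km/year.
    """

    years: np.ndarray
    intensities: np.ndarray
    bev_efficiency: float = 6.5    # km/kWh
    bev_distance: float = 15_180.0  # km/year

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=int)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "years", y)
        object.__setattr__(self, "intensities", i)
        if y.shape != i.shape or y.ndim != 1 or len(y) < 2:
            raise ValueError("need matching year/intensity vectors")
        if np.any(np.diff(y) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("grid intensity must be non-negative")
        if self.bev_efficiency <= 0:
            raise ValueError("BEV efficiency must be positive")
        if self.bev_distance <= 0:
            raise ValueError("BEV annual distance must be positive")

    @classmethod
    def default(cls, anchors: dict[int, float] | None = None,
                ) -> "GridIntensitySeries":
        anchors = anchors or {2020: 180.0, 2030: 30.0, 2035: 2.0, 2050: 1.0}
        xs = sorted(anchors)
        years = np.arange(xs[0], xs[-1] + 1)
        vals = np.interp(years, xs, [anchors[x] for x in xs])
        return cls(years=years, intensities=vals)

    def intensity(self, year: int) -> float:
        """g/kWh in a calendar year, clamped to the series' end values."""
        return float(np.interp(year, self.years, self.intensities))

    @classmethod
    def from_file(cls, path, **kwargs) -> "GridIntensitySeries":
        df = pd.read_csv(path).sort_values("year")
        return cls(years=df["year"].to_numpy(),
                   intensities=df["intensity_g_per_kwh"].to_numpy(), **kwargs)


def bev_annual_co2(intensity: float, grid: GridIntensitySeries) -> float:
    """Annual charging emissions (tonnes CO2e/vehicle/year) at a grid intensity.

    The annual energy drawn is distance over efficiency (kWh); multiplied by
    the intensity (g/kWh) and converted to tonnes.
    """
    if intensity < 0:
        raise ValueError("grid intensity must be non-negative")
    return (grid.bev_distance / grid.bev_efficiency) * intensity / 1e6


def bev_lifetime_co2(cohort_year: int, horizon_year: int,
                     schedule: SurvivalSchedule, grid: GridIntensitySeries) -> float:
    """Expected charging emissions (tonnes/vehicle) of a cohort's vehicle.

    Sums annual charging emissions from the cohort year to the horizon
    (inclusive), each year weighted by the fraction of the cohort still in
    service.
    """
    if horizon_year < cohort_year:
        raise ValueError("horizon must not precede the cohort year")
    return sum(
        schedule.survival(y - cohort_year) * bev_annual_co2(grid.intensity(y), grid)
        for y in range(cohort_year, horizon_year + 1))


def cumulative_co2(spec: ScenarioSpec, horizon: int, profiles: CohortProfiles,
                   schedule: SurvivalSchedule, grid: GridIntensitySeries | None = None,
                   sales: SalesTrajectory | None = None,
                   start_year: int = POLICY_START) -> float:
    """Cumulative CO2(e) in Mt from cohorts ``start_year..horizon`` to the horizon."""
    grid = grid or GridIntensitySeries.default()
    sales = sales or SalesTrajectory(base_year_sales=profiles.total_registrations)
    total_t = 0.0
    for cohort in range(start_year, horizon + 1):
        cohort_counts = compose_cohort(spec, cohort, profiles, sales)
        surv_sum = sum(schedule.survival(y - cohort)
                       for y in range(cohort, horizon + 1))
        bev_per_vehicle = bev_lifetime_co2(cohort, horizon, schedule, grid)
        for (seg, fuel), n in cohort_counts.items():
            if fuel == "bev":
                total_t += n * bev_per_vehicle
            else:
                total_t += n * profiles.co2_rate_for(seg, fuel) * surv_sum
    return total_t / 1e6


def annual_co2_new_sales(spec: ScenarioSpec, year: int, profiles: CohortProfiles,
                         sales: SalesTrajectory | None = None,
                         grid: GridIntensitySeries | None = None) -> float:
    """First-year annual CO2 (Mt) of the year's new registrations."""
    grid = grid or GridIntensitySeries.default()
    counts = compose_cohort(spec, year, profiles, sales)
    total = 0.0
    for (seg, fuel), n in counts.items():
        if fuel == "bev":
            total += n * bev_annual_co2(grid.intensity(year), grid)
        else:
            total += n * profiles.co2_rate_for(seg, fuel)
    return total / 1e6


def value_carbon(saving_mt: float, price_gbp_per_tonne: float) -> float:
    """Value (GBP billions) of an emission saving at a carbon price."""
    if price_gbp_per_tonne <= 0:
        raise ValueError("carbon price must be positive")
    return saving_mt * price_gbp_per_tonne / 1000.0


def cumulative_table(profiles: CohortProfiles, schedule: SurvivalSchedule,
                     grid: GridIntensitySeries | None = None,
                     sales: SalesTrajectory | None = None,
                     horizons: tuple[int, ...] = (2035, 2050),
                     scenarios: dict[str, ScenarioSpec] | None = None) -> pd.DataFrame:
    """Cumulative Mt per scenario and horizon, with % change versus BAU."""
    scenarios = scenarios or SCENARIOS
    rows = []
    totals = {
        (name, h): cumulative_co2(spec, h, profiles, schedule, grid, sales)
        for name, spec in scenarios.items() for h in horizons
    }
    for name in scenarios:
        row: dict[str, object] = {"scenario": name}
        for h in horizons:
            row[f"cumulative_mt_{h}"] = totals[(name, h)]
            bau = totals[("BAU", h)]
            row[f"pct_change_vs_bau_{h}"] = 100.0 * (totals[(name, h)] / bau - 1.0)
        rows.append(row)
    return pd.DataFrame(rows)


def valuation_table(cumulative: pd.DataFrame,
                    prices: dict[int, dict[str, float]] | None = None) -> pd.DataFrame:
    """Value of each scenario's saving versus BAU (GBP billions) by price level."""
    prices = prices or CARBON_PRICES
    bau = cumulative.set_index("scenario")
    rows = []
    for name, row in bau.iterrows():
        if name == "BAU":
            continue
        out: dict[str, object] = {"scenario": name}
        for h, levels in prices.items():
            saving = bau.loc["BAU", f"cumulative_mt_{h}"] - row[f"cumulative_mt_{h}"]
            for level, price in levels.items():
                out[f"value_bn_{h}_{level}"] = value_carbon(saving, price)
        rows.append(out)
    return pd.DataFrame(rows)
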