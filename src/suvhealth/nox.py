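"""Whole-fleet NOx projection and the implied urban NO2 change versus BAU.

Unlike the CO2 account (new cohorts only), ambient NO2 depends on the whole
on-road fleet, so the legacy (pre-policy) stock matters: older vehicles are
assumed to emit at the maximum European emission-standard NOx limit in force
in their first year of registration, and are retired along the survival
schedule.  New cohorts emit at the 2020 per-vehicle segment means
indefinitely.  Fleet NOx under a scenario, relative to BAU, scales the
assumed constant urban-background NO2 contribution of passenger cars
(2.59 ug/m3) proportionally, giving the concentration reduction that drives
the life-table health model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fleet import DistanceAssumptions
from .scenarios import (SCENARIOS, CohortProfiles, SalesTrajectory,
                        ScenarioSpec, compose_cohort, POLICY_START)
from .turnover import SurvivalSchedule

__all__ = [
    "EuroLimitTable",
    "LegacyComposition",
    "ConcentrationDelta",
    "NO2_BASELINE",
    "legacy_fleet_nox",
    "fleet_annual_nox",
    "no2_delta",
    "delta_series",
]

#: Assumed constant urban-background NO2 from UK passenger cars under BAU (ug/m3).
NO2_BASELINE = 2.59

#: Default era-step NOx limits (mg/km) by fuel and first-registration year.
#: Pre-2001 values are type-approval-era proxies.  Fully overridable.
DEFAULT_EURO_LIMITS: dict[str, list[tuple[int, int, float]]] = {
    "diesel": [(0, 2000, 900.0), (2001, 2005, 500.0), (2006, 2010, 250.0),
               (2011, 2014, 180.0), (2015, 9999, 80.0)],
    "petrol": [(0, 2000, 500.0), (2001, 2005, 150.0), (2006, 2010, 80.0),
               (2011, 9999, 60.0)],
}


@dataclass(frozen=True)
class EuroLimitTable:
    """Maximum NOx limit (mg/km) by fuel and first-registration year."""

    limits: dict[str, list[tuple[int, int, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EURO_LIMITS.items()})

    def __post_init__(self) -> None:
        for fuel, rows in self.limits.items():
            for lo, hi, lim in rows:
                if lim <= 0:
                    raise ValueError(f"{fuel} limit for {lo}-{hi} must be positive")

    def limit(self, fuel: str, registration_year: int) -> float:
        rows = self.limits.get(fuel)
        if rows is None:
            raise KeyError(f"no NOx limits for fuel {fuel!r}")
        for lo, hi, lim in rows:
            if lo <= registration_year <= hi:
                return lim
        raise KeyError(f"no NOx limit for fuel {fuel!r}, year {registration_year}")

    @classmethod
    def from_file(cls, path) -> "EuroLimitTable":
        df = pd.read_csv(path)
        limits: dict[str, list[tuple[int, int, float]]] = {}
        for row in df.itertuples(index=False):
            limits.setdefault(str(row.fuel), []).append(
                (int(row.year_from), int(row.year_to), float(row.limit_mg_per_km)))
        return cls(limits=limits)


@dataclass(frozen=True)
class LegacyComposition:
    """Pre-policy cohort sizes and fuel mix by registration year.

    Default: constant historical sales equal to the steady post-policy level
    (2.5 M/year) with a 45% diesel share, covering every cohort young enough
    to still be on the road at policy start.
    """

    first_year: int = 1995
    last_year: int = 2019
    annual_sales: float = 2_500_000.0
    diesel_share: float = 0.45

    def __post_init__(self) -> None:
        if not 0 <= self.diesel_share <= 1:
            raise ValueError("diesel share must be in [0, 1]")
        if self.annual_sales < 0:
            raise ValueError("annual sales must be non-negative")

    def cohorts(self) -> list[tuple[int, dict[str, float]]]:
        mix = {"diesel": self.diesel_share, "petrol": 1.0 - self.diesel_share}
        return [(y, {f: s * self.annual_sales for f, s in mix.items()})
                for y in range(self.first_year, self.last_year + 1)]


@dataclass(frozen=True)
class ConcentrationDelta:
    """Urban NO2 reduction versus BAU (ug/m3) in one calendar year."""

    year: int
    delta_no2: float
    baseline_no2: float = NO2_BASELINE

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_no2 <= self.baseline_no2 + 1e-12:
            raise ValueError(
                f"delta {self.delta_no2} outside [0, {self.baseline_no2}]")


def legacy_fleet_nox(year: int, legacy: LegacyComposition | None = None,
                     limits: EuroLimitTable | None = None,
                     distances: DistanceAssumptions | None = None,
                     schedule: SurvivalSchedule | None = None) -> float:
    """Annual NOx (tonnes) from the surviving pre-policy fleet in ``year``.

    Each pre-2020 cohort's survivors emit at the era NOx limit of their
    registration year over the fuel-class annual distance.
    """
    from .turnover import default_survival
    legacy = legacy or LegacyComposition()
    limits = limits or EuroLimitTable()
    distances = distances or DistanceAssumptions()
    schedule = schedule or default_survival()
    total = 0.0
    for reg_year, fuels in legacy.cohorts():
        age = year - reg_year
        if age < 0 or age > schedule.max_age:
            continue
        s = schedule.survival(age)
        for fuel, n in fuels.items():
            lim = limits.limit(fuel, reg_year)
            total += n * s * lim * distances.for_fuel(fuel) / 1e9
    return total


def fleet_annual_nox(spec: ScenarioSpec, year: int, profiles: CohortProfiles,
                     schedule: SurvivalSchedule,
                     sales: SalesTrajectory | None = None,
                     legacy: LegacyComposition | None = None,
                     limits: EuroLimitTable | None = None,
                     distances: DistanceAssumptions | None = None) -> float:
    """Whole-fleet NOx (tonnes/year): legacy survivors plus post-2020 cohorts.

    New internal-combustion cohorts emit at the 2020 per-vehicle segment
    means for as long as they survive; battery-electric vehicles emit none.
    """
    if year < POLICY_START:
        raise ValueError(f"year must be >= {POLICY_START}")
    total = legacy_fleet_nox(year, legacy, limits, distances, schedule)
    sales = sales or SalesTrajectory(base_year_sales=profiles.total_registrations)
    for cohort in range(POLICY_START, year + 1):
        s = schedule.survival(year - cohort)
        if s == 0.0:
            continue
        counts = compose_cohort(spec, cohort, profiles, sales)
        for (seg, fuel), n in counts.items():
            if fuel == "bev":
                continue
            total += n * s * profiles.nox_rate_for(seg, fuel) / 1000.0
    return total


def no2_delta(year: int, bau_nox: float, scen_nox: float,
              baseline: float = NO2_BASELINE) -> ConcentrationDelta:
    """NO2 reduction versus BAU from the proportional fleet-NOx change."""
    if bau_nox <= 0:
        raise ValueError("BAU fleet NOx must be positive")
    delta = baseline * (1.0 - scen_nox / bau_nox)
    delta = min(max(delta, 0.0), baseline)
    return ConcentrationDelta(year=year, delta_no2=delta, baseline_no2=baseline)


def delta_series(spec: ScenarioSpec, years: range, profiles: CohortProfiles,
                 schedule: SurvivalSchedule,
                 sales: SalesTrajectory | None = None,
                 legacy: LegacyComposition | None = None,
                 limits: EuroLimitTable | None = None,
                 distances: DistanceAssumptions | None = None,
                 baseline: float = NO2_BASELINE) -> pd.Series:
    """NO2 reduction versus BAU (ug/m3) for each year, as a series.

    This is the exposure input to the life-table health model.
    """
    bau = SCENARIOS["BAU"]
    out = {}
    for y in years:
        b = fleet_annual_nox(bau, y, profiles, schedule, sales, legacy, limits, distances)
        s = fleet_annual_nox(spec, y, profiles, schedule, sales, legacy, limits, distances)
        out[y] = no2_delta(y, b, s, baseline).delta_no2
    return pd.Series(out)
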