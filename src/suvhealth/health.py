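"""Life-table estimation and valuation of mortality impacts of NO2 changes.

The machinery follows the classical impact-assessment life table: a baseline
population by sex and single year of age evolves year by year under constant
baseline hazards, constant annual births and a constant age structure of
entry; a policy scenario multiplies the hazard at ages 30+ by a relative risk
derived from the (lagged) change in ambient NO2, and the health impact is the
difference in person-years lived between the impacted and baseline
projections, summed over all current and future cohorts up to a horizon year
(2126 by default, ~106 years after policy start so every cohort alive at
baseline completes its life course).

Concentration-response: all-cause mortality relative risk 1.023
(95% CI 1.008-1.037) per 10 ug/m3 NO2, applied at ages 30 and over.  A
reduction delta (ug/m3) therefore scales hazards by ``1.023**(-delta/10)``.

Inception lag: a concentration change phases in with 30% of its mortality
effect in the first year and the full effect from year 20, interpolated with
the standard distribution 30% (year 1), 50% spread over years 2-5, 20% over
years 6-20.

Valuation: life years are valued at a value-of-life-year (VOLY, default
GBP 60,000) and discounted (default 1.5%/year) to the policy start year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LifeTablePopulation",
    "ExposureResponse",
    "LagSchedule",
    "ValuationParams",
    "relative_risk",
    "lagged_delta",
    "life_years_gained",
    "value_life_years",
    "sensitivity_grid",
]

POOLED_HAZARD_FROM_AGE = 90  # single hazard assumed for ages 90..max_age


@dataclass(frozen=True)
class LifeTablePopulation:
    """Baseline population, deaths and derived hazards by sex and age 0..max.

    Hazards are annual death probabilities ``deaths/population`` per single
    year of age; on construction the hazards for ages 90+ are pooled (total
    deaths over total population at those ages), as assumed by the source
    mortality schedule.
    """

    population: dict[str, np.ndarray]
    deaths: dict[str, np.ndarray]
    annual_births: dict[str, float]
    base_year: int = 2019
    hazards: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        hazards: dict[str, np.ndarray] = {}
        for sex, pop in self.population.items():
            pop = np.asarray(pop, dtype=float)
            dth = np.asarray(self.deaths[sex], dtype=float)
            if pop.shape != dth.shape or pop.ndim != 1:
                raise ValueError(f"{sex}: population/deaths shape mismatch")
            if np.any(pop < 0) or np.any(dth < 0):
                raise ValueError(f"{sex}: negative population or deaths")
            if np.any(dth > pop):
                age = int(np.nonzero(dth > pop)[0][0])
                raise ValueError(f"{sex}: deaths exceed population at age {age}")
            self.population[sex] = pop
            self.deaths[sex] = dth
            with np.errstate(invalid="ignore", divide="ignore"):
                h = np.where(pop > 0, dth / np.where(pop > 0, pop, 1.0), 0.0)
            old = slice(POOLED_HAZARD_FROM_AGE, None)
            pool_pop = pop[old].sum()
            if pool_pop > 0:
                h[old] = dth[old].sum() / pool_pop
            bad = np.nonzero((h < 0) | (h > 1))[0]
            if bad.size:
                raise ValueError(f"{sex}: hazard outside [0, 1] at age {int(bad[0])}")
            hazards[sex] = h
        object.__setattr__(self, "hazards", hazards)

    @property
    def max_age(self) -> int:
        return len(next(iter(self.population.values()))) - 1

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self.population)

    def to_file(self, path: str | Path) -> None:
        rows = []
        for sex in self.sexes:
            for age in range(self.max_age + 1):
                rows.append({"sex": sex, "age": age,
                             "population": self.population[sex][age],
                             "deaths": self.deaths[sex][age]})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_file(cls, path: str | Path, base_year: int = 2019,
                  annual_births: Mapping[str, float] | None = None,
                  ) -> "LifeTablePopulation":
        """Read a (sex, age, population, deaths) CSV.

        Annual births default to the age-0 population of each sex.
        """
        df = pd.read_csv(path)
        need = {"sex", "age", "population", "deaths"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: population file needs columns {sorted(need)}")
        population: dict[str, np.ndarray] = {}
        deaths: dict[str, np.ndarray] = {}
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if not np.array_equal(ages, np.arange(len(ages))):
                raise ValueError(f"{path}: {sex} ages must run 0..max with no gaps")
            population[str(sex)] = grp["population"].to_numpy(dtype=float)
            deaths[str(sex)] = grp["deaths"].to_numpy(dtype=float)
        births = dict(annual_births) if annual_births else {
            s: float(population[s][0]) for s in population}
        return cls(population=population, deaths=deaths,
                   annual_births=births, base_year=base_year)


@dataclass(frozen=True)
class ExposureResponse:
    """All-cause mortality risk per 10 ug/m3 NO2, applied from ``min_age`` up."""

    rr_per_10ug: float = 1.023
    ci_low: float = 1.008
    ci_high: float = 1.037
    min_age: int = 30

    def __post_init__(self) -> None:
        if self.rr_per_10ug <= 0:
            raise ValueError("relative risk per 10 ug/m3 must be positive")


def relative_risk(delta: float, er: ExposureResponse | None = None) -> float:
    """Mortality relative risk for an NO2 *reduction* of ``delta`` ug/m3.

    Below 1 for reductions, above 1 for increases (negative delta).
    """
    er = er or ExposureResponse()
    return er.rr_per_10ug ** (-delta / 10.0)


@dataclass(frozen=True)
class LagSchedule:
    """Cumulative fraction of the mortality effect by years since the change.

    ``cumulative[k-1]`` is the fraction of the full effect realised k years
    after a step change; 30% in year 1 and 100% from year 20 onwards.
    """

    cumulative: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cumulative, dtype=float)
        object.__setattr__(self, "cumulative", c)
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("cumulative lag fractions must be non-decreasing")
        if not np.isclose(c[-1], 1.0):
            raise ValueError("lag schedule must reach 1.0 at its final year")

    @classmethod
    def epa_default(cls) -> "LagSchedule":
        """30% in year 1, 50% evenly over years 2-5, 20% evenly over years 6-20."""
        inc = np.concatenate([[0.30], np.full(4, 0.50 / 4), np.full(15, 0.20 / 15)])
        return cls(np.cumsum(inc))

    def fraction(self, years_since: int) -> float:
        """Cumulative effect fraction ``years_since`` years after a change."""
        if years_since <= 0:
            return 0.0
        if years_since >= len(self.cumulative):
            return 1.0
        return float(self.cumulative[years_since - 1])


def lagged_delta(delta_series: "pd.Series | Mapping[int, float]",
                 lag: LagSchedule | None = None) -> pd.Series:
    """Effective (lag-weighted) concentration change by calendar year.

    The series of raw annual reductions is decomposed into year-on-year
    increments; each increment phases in according to the cumulative lag.  A
    single step change reaches 30% of its effect in its first year and 100%
    from year 20.
    """
    lag = lag or LagSchedule.epa_default()
    s = pd.Series(dict(delta_series)).sort_index()
    years = s.index.to_numpy()
    inc = np.diff(np.concatenate([[0.0], s.to_numpy(dtype=float)]))
    eff = np.zeros(len(years))
    for j, dj in enumerate(inc):
        if dj == 0.0:
            continue
        for t in range(j, len(years)):
            eff[t] += dj * lag.fraction(int(years[t] - years[j]) + 1)
    return pd.Series(eff, index=s.index)


@dataclass(frozen=True)
class ValuationParams:
    """Monetisation of life years: VOLY (GBP/life-year) and discount rate."""

    voly: float = 60_000.0
    discount_rate: float = 0.015

    def __post_init__(self) -> None:
        if self.voly <= 0:
            raise ValueError("VOLY must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")


def _project_person_years(pop: LifeTablePopulation, rr_by_year: Mapping[int, float],
                          min_age: int, end_year: int,
                          births_until: int | None) -> pd.Series:
    """Person-years lived per calendar year under given relative risks.

    End-of-year accounting: the population alive at the end of each year
    accrues one person-year.  Age ``max_age`` is terminal (no survivors pass
    beyond it).  Births enter at age 0 each year (until ``births_until``).
    """
    max_age = pop.max_age
    ages = np.arange(max_age + 1)
    py = {}
    state = {sex: pop.population[sex].copy() for sex in pop.sexes}
    for year in range(pop.base_year + 1, end_year + 1):
        rr = rr_by_year.get(year, 1.0)
        total = 0.0
        for sex in pop.sexes:
            h = pop.hazards[sex].copy()
            if rr != 1.0:
                h[ages >= min_age] = h[ages >= min_age] * rr
            bad = np.nonzero((h < 0) | (h > 1))[0]
            if bad.size:
                raise ValueError(
                    f"modified hazard outside [0, 1] at age {int(bad[0])} "
                    f"({sex}, year {year}, RR {rr:.4f})")
            prev = state[sex]
            nxt = np.zeros_like(prev)
            survivors = prev * (1.0 - h)
            nxt[1:] = survivors[:-1]  # survivors of max_age exit the table
            if births_until is None or year <= births_until:
                nxt[0] = pop.annual_births[sex]
            state[sex] = nxt
            total += nxt.sum()
        py[year] = total
    return pd.Series(py)


def life_years_gained(pop: LifeTablePopulation,
                      delta_series: "pd.Series | Mapping[int, float]",
                      er: ExposureResponse | None = None,
                      lag: LagSchedule | None = None,
                      end_year: int = 2126,
                      apply_lag: bool = True,
                      births_until: int | None = None,
                      ) -> tuple[float, pd.Series]:
    """Life years gained versus baseline from a series of NO2 reductions.

    ``delta_series`` maps calendar year to the reduction in ambient NO2
    (ug/m3) versus the baseline scenario in that year; it is lag-weighted
    (unless ``apply_lag`` is false), converted to relative risks applied at
    ages ``er.min_age`` and over, and the difference in person-years between
    the impacted and baseline projections is accumulated through
    ``end_year``.  Returns the total and the per-calendar-year series.
    """
    er = er or ExposureResponse()
    s = pd.Series(dict(delta_series)).sort_index()
    # the last known reduction persists to the horizon year
    years = range(int(s.index.min()), end_year + 1)
    s = s.reindex(years).ffill()
    eff = lagged_delta(s, lag) if apply_lag else s
    rr_by_year = {int(y): relative_risk(float(d), er) for y, d in eff.items()}
    base = _project_person_years(pop, {}, er.min_age, end_year, births_until)
    scen = _project_person_years(pop, rr_by_year, er.min_age, end_year, births_until)
    gained = (scen - base).reindex(base.index)
    return float(gained.sum()), gained


def value_life_years(ly_by_year: "pd.Series | Mapping[int, float]",
                     params: ValuationParams | None = None,
                     base_year: int = 2020) -> float:
    """Discounted monetary value (GBP) of a stream of life years."""
    params = params or ValuationParams()
    s = pd.Series(dict(ly_by_year)).sort_index()
    t = s.index.to_numpy(dtype=float) - base_year
    return float((s.to_numpy(dtype=float) * params.voly
                  * (1.0 + params.discount_rate) ** (-t)).sum())


def sensitivity_grid(pop: LifeTablePopulation,
                     delta_series: "pd.Series | Mapping[int, float]",
                     volys: Iterable[float] = (20_000.0, 60_000.0),
                     rates: Iterable[float] = (0.015, 0.035),
                     coefficients: Iterable[float] = (1.008, 1.023, 1.037),
                     lag: LagSchedule | None = None,
                     end_year: int = 2126,
                     base_year: int = 2020) -> pd.DataFrame:
    """Valuation grid over VOLY x discount rate x concentration-response.

    One life-table projection per coefficient; every (VOLY, rate) cell reuses
    the same life-year stream, so VOLY rows are related by exact linearity.
    Values in GBP.
    """
    ly_streams = {}
    for coef in coefficients:
        er = ExposureResponse(rr_per_10ug=coef)
        _, by_year = life_years_gained(pop, delta_series, er=er, lag=lag,
                                       end_year=end_year)
        ly_streams[coef] = by_year
    rows = []
    for voly in volys:
        for rate in rates:
            params = ValuationParams(voly=voly, discount_rate=rate)
            row = {"voly": voly, "discount_rate": rate}
            for coef, stream in ly_streams.items():
                row[f"rr_{coef}"] = value_life_years(stream, params, base_year)
            rows.append(row)
    return pd.DataFrame(rows)
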