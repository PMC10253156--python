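import numpy as np
import pandas as pd
import pytest

from suvhealth.health import (ExposureResponse, LagSchedule,
                              LifeTablePopulation, ValuationParams,
                              lagged_delta, life_years_gained, relative_risk,
                              sensitivity_grid, value_life_years)


class TestRelativeRisk:
    def test_no_change_is_unity(self):
        assert relative_risk(0.0) == 1.0

    def test_ten_microgram_reduction(self):
        assert relative_risk(10.0) == pytest.approx(1 / 1.023, rel=1e-9)
        assert relative_risk(10.0) == pytest.approx(0.977517, abs=1e-6)

    def test_concentration_increase_raises_risk(self):
        assert relative_risk(-5.0) > 1.0

    def test_monotone_decreasing_in_delta(self):
        deltas = np.linspace(-2, 3, 11)
        rrs = [relative_risk(d) for d in deltas]
        assert all(b < a for a, b in zip(rrs, rrs[1:]))

    def test_invalid_coefficient_rejected(self):
        with pytest.raises(ValueError):
            ExposureResponse(rr_per_10ug=0.0)


class TestLagSchedule:
    def test_epa_anchors(self):
        lag = LagSchedule.epa_default()
        assert lag.fraction(1) == pytest.approx(0.30)
        assert lag.fraction(20) == pytest.approx(1.0)
        assert lag.fraction(25) == 1.0
        assert lag.fraction(0) == 0.0

    def test_cumulative_non_decreasing(self):
        c = LagSchedule.epa_default().cumulative
        assert (np.diff(c) >= 0).all()

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            LagSchedule(np.array([0.5, 0.4, 1.0]))
        with pytest.raises(ValueError):
            LagSchedule(np.array([0.3, 0.6, 0.9]))

    def test_step_change_phase_in(self):
        years = range(2020, 2045)
        series = pd.Series(2.0, index=years)  # step of 2 ug/m3 in 2020
        eff = lagged_delta(series)
        assert eff[2020] == pytest.approx(0.30 * 2.0)
        assert eff[2039] == pytest.approx(2.0)   # year 20 of the change
        assert eff[2044] == pytest.approx(2.0)

    def test_zero_series_stays_zero(self):
        eff = lagged_delta(pd.Series(0.0, index=range(2020, 2030)))
        assert (eff == 0).all()


class TestLifeTablePopulation:
    def test_old_age_hazards_pooled(self, population):
        for sex in population.sexes:
            h = population.hazards[sex]
            assert np.allclose(h[90:], h[90])

    def test_deaths_exceeding_population_rejected(self):
        pop = np.full(106, 100.0)
        deaths = np.zeros(106)
        deaths[50] = 200.0
        with pytest.raises(ValueError, match="age 50"):
            LifeTablePopulation(population={"female": pop},
                                deaths={"female": deaths},
                                annual_births={"female": 100.0})

    def test_file_roundtrip(self, population, tmp_path):
        path = tmp_path / "pop.csv"
        population.to_file(path)
        back = LifeTablePopulation.from_file(
            path, base_year=population.base_year,
            annual_births=population.annual_births)
        for sex in population.sexes:
            np.testing.assert_allclose(back.population[sex],
                                       population.population[sex])
            np.testing.assert_allclose(back.hazards[sex],
                                       population.hazards[sex])


def _ramp_delta(start=2020, full_by=2050, level=2.5, until=2060):
    years = np.arange(start, until + 1)
    vals = np.clip((years - start) / (full_by - start), 0, 1) * level
    return pd.Series(vals, index=years)


def _person_years_oracle(pop, rr_by_year, min_age, end_year):
    """Explicit per-cohort survival-product bookkeeping (independent oracle)."""
    total_by_year = {y: 0.0 for y in range(pop.base_year + 1, end_year + 1)}
    for sex in pop.sexes:
        h0 = pop.hazards[sex]
        cohorts = [(pop.base_year, a, float(pop.population[sex][a]))
                   for a in range(pop.max_age + 1)]
        cohorts += [(y, -1, float(pop.annual_births[sex]))
                    for y in range(pop.base_year + 1, end_year + 1)]
        for (y0, a0, n) in cohorts:
            if n == 0:
                continue
            if a0 == -1:  # born during y0: one full person-year at age 0
                total_by_year[y0] += n
                a0, surv = 0, 1.0
            else:
                surv = 1.0
            for y in range(y0 + 1, end_year + 1):
                age = a0 + (y - y0 - 1)
                if age >= pop.max_age:
                    break
                h = h0[age]
                if age >= min_age:
                    h = h * rr_by_year.get(y, 1.0)
                surv *= 1.0 - h
                total_by_year[y] += n * surv
    return pd.Series(total_by_year)


class TestLifeYearsGained:
    def test_null_scenario_conserves_person_years_exactly(self, population):
        zero = pd.Series(0.0, index=range(2020, 2060))
        total, by_year = life_years_gained(population, zero, end_year=2080)
        assert total == 0.0
        assert (by_year == 0.0).all()

    def test_matches_microsimulation_oracle(self, population):
        """Array projection equals per-cohort survival products to 1e-6."""
        from suvhealth.health import lagged_delta as _ld
        delta = _ramp_delta(until=2060)
        end_year = 2060
        er = ExposureResponse()
        eff = _ld(delta.reindex(range(2020, end_year + 1)).ffill())
        rr = {int(y): relative_risk(float(d), er) for y, d in eff.items()}
        scen = _person_years_oracle(population, rr, er.min_age, end_year)
        base = _person_years_oracle(population, {}, er.min_age, end_year)
        expected = float((scen - base).sum())
        total, _ = life_years_gained(population, delta, end_year=end_year)
        assert total == pytest.approx(expected, rel=1e-6)

    def test_under_30s_contribute_no_change(self):
        """A population that never reaches the minimum age shows zero gain."""
        n_ages = 41
        pop = np.zeros(n_ages)
        pop[:11] = 1000.0
        deaths = pop * 0.001
        young = LifeTablePopulation(
            population={"female": pop}, deaths={"female": deaths},
            annual_births={"female": 0.0}, base_year=2019)
        delta = pd.Series(2.59, index=range(2020, 2031))
        total, _ = life_years_gained(young, delta, end_year=2037)
        assert total == 0.0

    def test_monotone_in_coefficient_and_delta(self, population):
        delta = _ramp_delta()
        totals = [life_years_gained(population, delta,
                                    er=ExposureResponse(rr_per_10ug=c),
                                    end_year=2080)[0]
                  for c in (1.008, 1.023, 1.037)]
        assert totals[0] < totals[1] < totals[2]
        half, _ = life_years_gained(population, delta / 2, end_year=2080)
        assert half < totals[1]

    def test_lag_reduces_gain_by_small_margin(self, population):
        """The inception lag costs a few percent of the life years gained."""
        delta = _ramp_delta()
        lagged, _ = life_years_gained(population, delta, end_year=2126)
        unlagged, _ = life_years_gained(population, delta, end_year=2126,
                                        apply_lag=False)
        cost = 1.0 - lagged / unlagged
        assert 0.02 < cost < 0.08

    def test_modified_hazard_above_one_rejected(self):
        pop = np.full(106, 1000.0)
        deaths = np.zeros(106)
        deaths[50:] = 970.0
        risky = LifeTablePopulation(
            population={"male": pop}, deaths={"male": deaths},
            annual_births={"male": 1000.0}, base_year=2019)
        increase = pd.Series(-30.0, index=range(2020, 2030))  # worsening air
        with pytest.raises(ValueError, match="hazard"):
            life_years_gained(risky, increase, end_year=2040)


class TestValuation:
    def test_zero_rate_is_voly_times_total(self):
        stream = pd.Series([100.0, 200.0], index=[2030, 2040])
        got = value_life_years(stream, ValuationParams(voly=60_000,
                                                       discount_rate=0.0))
        assert got == pytest.approx(300.0 * 60_000)

    def test_halving_voly_halves_value(self):
        stream = pd.Series([50.0, 75.0], index=[2025, 2035])
        v60 = value_life_years(stream, ValuationParams(voly=60_000))
        v30 = value_life_years(stream, ValuationParams(voly=30_000))
        assert v30 == pytest.approx(v60 / 2, rel=1e-12)

    def test_discounting_references_policy_start(self):
        stream = pd.Series([100.0], index=[2030])
        got = value_life_years(stream, ValuationParams(voly=1.0,
                                                       discount_rate=0.015))
        assert got == pytest.approx(100.0 * 1.015 ** -10, rel=1e-12)


@pytest.fixture(scope="module")
def grid(population):
    return sensitivity_grid(population, _ramp_delta(), end_year=2080)


class TestSensitivityGrid:
    def test_monotone_across_coefficient_columns(self, grid):
        cols = ["rr_1.008", "rr_1.023", "rr_1.037"]
        for _, row in grid.iterrows():
            assert row[cols[0]] < row[cols[1]] < row[cols[2]]

    def test_voly_rows_related_by_exact_factor_three(self, grid):
        g = grid.set_index(["voly", "discount_rate"])
        for rate in (0.015, 0.035):
            for col in ("rr_1.008", "rr_1.023", "rr_1.037"):
                ratio = g.loc[(60_000.0, rate), col] / g.loc[(20_000.0, rate), col]
                assert ratio == pytest.approx(3.0, rel=1e-12)

    def test_higher_discount_rate_strictly_smaller(self, grid):
        g = grid.set_index(["voly", "discount_rate"])
        for voly in (20_000.0, 60_000.0):
            assert g.loc[(voly, 0.035), "rr_1.023"] < g.loc[(voly, 0.015), "rr_1.023"]
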