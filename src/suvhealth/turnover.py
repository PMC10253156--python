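"""Vehicle stock turnover: cohort survival and fleet-penetration calibration.

A sales cohort of vehicles attrits with age.  The survival schedule S(a) is
the fraction of a cohort still in service at integer age a, with S(0)=1,
S non-increasing, a median service life of 14 years (S(14)=0.5) and complete
retirement by ``max_age`` (default 25).  The default schedule interpolates
those anchors piecewise-linearly, giving an expected service life
sum(S) = 13.75 years, consistent with the 14-year median.

Fleet penetration ("coverage") of a policy applied to new sales from the
policy year onwards is the post-policy share of the total on-road stock.
The published milestones for the UK fleet — 41% after 5 years, 77% after 10,
96% after 15 — cannot be reproduced by a constant-sales steady-state fleet:
under any non-increasing schedule the mean survival over ages 0..5 is at
least the mean over ages 6..10, but the milestones would require
0.41/6 < 0.36/5 (see :func:`steady_state_feasibility`).  The milestones
instead embed the real age structure of the pre-policy fleet, which was
weighted towards older cohorts.  Calibration therefore solves for a
three-level legacy-fleet age profile (one level per milestone interval) that
reproduces all three milestones exactly while the survival schedule keeps
every published survival fact exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalSchedule",
    "CalibratedTurnover",
    "InfeasibleCalibrationError",
    "default_survival",
    "calibrate_survival",
    "surviving_count",
    "steady_state_feasibility",
]

DEFAULT_MILESTONES = {5: 0.41, 10: 0.77, 15: 0.96}
DEFAULT_MEDIAN_AGE = 14
DEFAULT_MAX_AGE = 25


class InfeasibleCalibrationError(ValueError):
    """Raised when no non-negative calibration satisfies the constraints."""


@dataclass(frozen=True)
class SurvivalSchedule:
    """Surviving fraction of a sales cohort at integer ages 0..max_age."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.ndim != 1 or len(f) < 2:
            raise ValueError("survival schedule needs fractions at ages 0..max_age")
        if not np.isclose(f[0], 1.0):
            raise ValueError("S(0) must be 1 (whole cohort in service in year of sale)")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("survival fractions must be non-increasing with age")
        if not np.isclose(f[-1], 0.0):
            raise ValueError("S(max_age) must be 0 (cohort fully retired)")

    @property
    def max_age(self) -> int:
        return len(self.fractions) - 1

    @property
    def expected_lifespan(self) -> float:
        """Expected years in service per vehicle, sum of S(a) over all ages."""
        return float(self.fractions.sum())

    def survival(self, age: int) -> float:
        """S(age); zero beyond max_age."""
        if age < 0:
            raise ValueError(f"vehicle age must be non-negative, got {age}")
        if age > self.max_age:
            return 0.0
        return float(self.fractions[age])

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"age": np.arange(len(self.fractions)),
                      "surviving_fraction": self.fractions}).to_csv(path, index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "SurvivalSchedule":
        df = pd.read_csv(path)
        df = df.sort_values("age")
        ages = df["age"].to_numpy()
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ValueError(f"{path}: ages must be consecutive integers from 0")
        return cls(df["surviving_fraction"].to_numpy(dtype=float))


def default_survival(median_age: int = DEFAULT_MEDIAN_AGE,
                     max_age: int = DEFAULT_MAX_AGE) -> SurvivalSchedule:
    """Piecewise-linear survival through (0, 1), (median_age, 0.5), (max_age, 0)."""
    if not 0 < median_age < max_age:
        raise ValueError("need 0 < median_age < max_age")
    ages = np.arange(max_age + 1, dtype=float)
    f = np.interp(ages, [0.0, float(median_age), float(max_age)], [1.0, 0.5, 0.0])
    return SurvivalSchedule(f)


def surviving_count(cohort_size: float, cohort_year: int, calendar_year: int,
                    schedule: SurvivalSchedule) -> float:
    """Vehicles of a cohort still in service in ``calendar_year``.

    A vehicle registered in year y is age 0 (fully in service) during y.
    """
    age = calendar_year - cohort_year
    if age < 0:
        raise ValueError(
            f"calendar year {calendar_year} precedes cohort year {cohort_year}")
    if cohort_size < 0:
        raise ValueError("cohort size must be non-negative")
    return cohort_size * schedule.survival(age)


def steady_state_feasibility(milestones: dict[int, float]) -> pd.DataFrame:
    """Diagnose the constant-sales steady-state reading of the milestones.

    In a steady-state fleet with constant annual sales, coverage at policy age
    y is sum(S(0..y))/sum(S), so consecutive milestones fix the mean survival
    per age inside each interval (0..y1, y1+1..y2, ...), in units of the total
    fleet stock.  A non-increasing schedule requires those interval means to be
    non-increasing too.  Returns one row per interval with its required mean;
    ``feasible`` is False on any interval whose required mean exceeds the
    previous interval's, certifying that no non-increasing survival schedule
    can reproduce the milestones under the steady-state reading.
    """
    ages = sorted(milestones)
    edges = [-1] + ages
    covs = [0.0] + [milestones[y] for y in ages]
    rows = []
    prev_mean = np.inf
    for (a0, a1), (c0, c1) in zip(zip(edges, edges[1:]), zip(covs, covs[1:])):
        n_ages = a1 - a0
        mean = (c1 - c0) / n_ages  # required mean S per age, per unit fleet stock
        rows.append({"ages": f"{a0 + 1}..{a1}", "required_mean_survival": mean,
                     "feasible": mean <= prev_mean + 1e-12})
        prev_mean = mean
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibratedTurnover:
    """Survival schedule plus the calibrated legacy-fleet age profile.

    ``legacy_weights[b]`` (b = 1..max_age-1) is the original sales volume of
    the cohort that was b years old at policy start, in units of the constant
    post-policy annual sales.  Its surviving stock at policy age y is
    ``legacy_weights[b] * S(b + y)``.
    """

    schedule: SurvivalSchedule
    legacy_weights: np.ndarray
    milestones: dict[int, float] = field(default_factory=dict)

    def post_policy_stock(self, policy_age: int) -> float:
        """Stock of post-policy cohorts (ages 0..policy_age) per unit annual sales."""
        return float(self.schedule.fractions[: policy_age + 1].sum())

    def legacy_stock(self, policy_age: int) -> float:
        """Surviving pre-policy stock at the given policy age."""
        S = self.schedule
        return float(sum(w * S.survival(b + policy_age)
                         for b, w in enumerate(self.legacy_weights) if w))

    def fleet_coverage(self, policy_age: int) -> float:
        """Post-policy share of the total on-road fleet, ``policy_age`` years in."""
        post = self.post_policy_stock(policy_age)
        return post / (post + self.legacy_stock(policy_age))


def calibrate_survival(milestones: dict[int, float] | None = None,
                       median_age: int = DEFAULT_MEDIAN_AGE,
                       max_age: int = DEFAULT_MAX_AGE) -> CalibratedTurnover:
    """Calibrate stock turnover to the published fleet-penetration milestones.

    The survival schedule is fixed by its published anchors (S(0)=1,
    S(median)=0.5, S(max_age)=0, piecewise linear).  The pre-policy fleet age
    profile is piecewise constant over the milestone intervals
    (1..y1, y1+1..y2, y2+1..max_age-1) and solved from the linear system that
    makes coverage at each milestone age exact.

    Raises
    ------
    InfeasibleCalibrationError
        If the milestones are not strictly increasing in (0, 1), the linear
        system is singular, or the implied legacy profile is negative.
    """
    milestones = dict(DEFAULT_MILESTONES if milestones is None else milestones)
    ages = sorted(milestones)
    if len(ages) < 1 or ages[-1] >= max_age:
        raise InfeasibleCalibrationError(
            f"milestone ages {ages} must lie inside (0, max_age={max_age})")
    covs = [milestones[y] for y in ages]
    if any(not 0 < c < 1 for c in covs) or any(
            c2 <= c1 for c1, c2 in zip(covs, covs[1:])):
        raise InfeasibleCalibrationError(
            f"milestone coverages {covs} must be strictly increasing within (0, 1)")

    schedule = default_survival(median_age=median_age, max_age=max_age)
    S = schedule.fractions

    # One legacy level per milestone interval: ages-at-policy-start
    # 1..y1, y1+1..y2, ..., y_{k-1}+1..max_age-1.
    bounds = [1] + [y + 1 for y in ages[:-1]] + [max_age]
    ranges = [range(bounds[i], bounds[i + 1]) for i in range(len(ages))]

    A = np.zeros((len(ages), len(ranges)))
    rhs = np.zeros(len(ages))
    for i, y in enumerate(ages):
        post = S[: y + 1].sum()
        rhs[i] = post * (1.0 - covs[i]) / covs[i]  # legacy stock required at age y
        for j, rng in enumerate(ranges):
            A[i, j] = sum(S[b + y] if b + y <= max_age else 0.0 for b in rng)
    try:
        levels = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise InfeasibleCalibrationError(
            f"singular milestone system (matrix {A.tolist()})") from exc
    if np.any(levels < -1e-9):
        raise InfeasibleCalibrationError(
            "milestones imply a negative legacy-fleet age profile: "
            f"levels {levels.tolist()} on intervals {[list(r) for r in ranges]}")
    levels = np.clip(levels, 0.0, None)

    weights = np.zeros(max_age)  # index = age at policy start (0 unused)
    for level, rng in zip(levels, ranges):
        for b in rng:
            weights[b] = level

    calib = CalibratedTurnover(schedule=schedule, legacy_weights=weights,
                               milestones=milestones)
    for y, c in milestones.items():
        got = calib.fleet_coverage(y)
        if abs(got - c) > 1e-9:
            raise InfeasibleCalibrationError(
                f"calibration failed to reproduce milestone {y}y: {got} != {c}")
    return calib
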