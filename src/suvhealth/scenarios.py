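"""Scenario engine: composition of new registrations by segment and fuel.

Five canonical scenarios contrast SUV sales policy with fleet
electrification:

* **BAU** — segment proportions, fuel mix and efficiency of new sales stay at
  their 2020 values indefinitely.
* **SmallSUV** — medium and large SUV sales are replaced 1:1 by small SUVs
  from 2020; otherwise as BAU.
* **NoSUV** — small, medium and large SUVs are replaced 1:1 by average
  B-, C- and D-segment cars respectively.
* **Electrified** — battery-electric share of new sales rises from its 2020
  level through anchors 25% (2025), 70% (2030) and 100% (2035), linearly
  interpolated; the residual keeps the 2020 petrol/diesel mix until 2030 and
  is all petrol plug-in hybrid over 2031-2035.
* **ElectrifiedSmallSUV** — the SmallSUV substitution applied first, then the
  Electrified uptake (this order is fixed: the two operators commute on
  counts but not on fuel mix).

Sales are the observed 2020 registration total in 2020 and a constant
2.5 million units/year from 2021.  Substituted vehicles adopt the target
segment's 2020 fuel mix and per-vehicle emission profile ("an average car of
the target segment").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fleet import (DistanceAssumptions, VehicleModelRecord, annual_model_co2,
                    annual_model_nox)

__all__ = [
    "ScenarioSpec",
    "SalesTrajectory",
    "CohortProfiles",
    "SCENARIOS",
    "bev_share",
    "compose_cohort",
]

BEV_ANCHORS_DEFAULT = {2025: 0.25, 2030: 0.70, 2035: 1.0}
POLICY_START = 2020
PHEV_FROM = 2031  # residual non-BEV sales are petrol PHEV from this year
PHEV_UNTIL = 2035


@dataclass(frozen=True)
class ScenarioSpec:
    """Segment-substitution rules and electrification trajectory for one scenario."""

    name: str
    substitutions: dict[str, str] = field(default_factory=dict)
    electrified: bool = False
    bev_anchors: dict[int, float] = field(
        default_factory=lambda: dict(BEV_ANCHORS_DEFAULT))
    phev_rule: bool = True

    def __post_init__(self) -> None:
        years = sorted(self.bev_anchors)
        shares = [self.bev_anchors[y] for y in years]
        if any(not 0 <= s <= 1 for s in shares):
            raise ValueError("BEV share anchors must lie in [0, 1]")
        if self.electrified and any(b < a for a, b in zip(shares, shares[1:])):
            raise ValueError("BEV share anchors must be non-decreasing")


SCENARIOS: dict[str, ScenarioSpec] = {
    "BAU": ScenarioSpec(name="BAU"),
    "SmallSUV": ScenarioSpec(
        name="SmallSUV",
        substitutions={"medium_suv": "small_suv", "large_suv": "small_suv"}),
    "NoSUV": ScenarioSpec(
        name="NoSUV",
        substitutions={"small_suv": "B", "medium_suv": "C", "large_suv": "D"}),
    "Electrified": ScenarioSpec(name="Electrified", electrified=True),
    "ElectrifiedSmallSUV": ScenarioSpec(
        name="ElectrifiedSmallSUV", electrified=True,
        substitutions={"medium_suv": "small_suv", "large_suv": "small_suv"}),
}


@dataclass(frozen=True)
class SalesTrajectory:
    """Annual new registrations: observed 2020 count, then constant sales."""

    base_year_sales: float = 1_560_452.0
    steady_sales: float = 2_500_000.0

    def __post_init__(self) -> None:
        if self.base_year_sales < 0 or self.steady_sales < 0:
            raise ValueError("sales must be non-negative")

    def sales(self, year: int) -> float:
        if year < POLICY_START:
            raise ValueError(f"no sales defined before {POLICY_START}")
        return self.base_year_sales if year == POLICY_START else self.steady_sales


class CohortProfiles:
    """2020 composition and per-vehicle annual emission rates by (segment, fuel).

    ``counts`` holds the 2020 registrations per (segment key, fuel) cell;
    ``co2_rate`` / ``nox_rate`` the mean annual tonnes (CO2) and kg (NOx) per
    vehicle per cell.  NOx rates average over NOx-reporting registrations of
    the cell, falling back to the segment's (then the fleet's) reporting ICE
    mean when a cell has no reported values.  Battery-electric cells are zero
    (their charging emissions enter through the grid model).  The fleet-wide
    petrol-PHEV averages stand in for PHEV sales in segments that had none in
    2020.
    """

    def __init__(self, counts: Mapping[tuple[str, str], float],
                 co2_rate: Mapping[tuple[str, str], float],
                 nox_rate: Mapping[tuple[str, str], float],
                 phev_co2_rate: float, phev_nox_rate: float):
        self.counts = dict(counts)
        self.co2_rate = dict(co2_rate)
        self.nox_rate = dict(nox_rate)
        self.phev_co2_rate = phev_co2_rate
        self.phev_nox_rate = phev_nox_rate

    @classmethod
    def from_records(cls, records: Iterable[VehicleModelRecord],
                     distances: DistanceAssumptions | None = None) -> "CohortProfiles":
        distances = distances or DistanceAssumptions()
        counts: dict[tuple[str, str], float] = {}
        co2_tot: dict[tuple[str, str], float] = {}
        nox_tot: dict[tuple[str, str], float] = {}
        nox_reg: dict[tuple[str, str], float] = {}
        for r in records:
            cell = (r.segment_key, r.fuel)
            d = distances.for_fuel(r.fuel)
            counts[cell] = counts.get(cell, 0.0) + r.registrations
            co2_tot[cell] = co2_tot.get(cell, 0.0) + annual_model_co2(
                r.co2_wltp, r.registrations, d)
            if r.nox_rde is not None:
                nox_reg[cell] = nox_reg.get(cell, 0.0) + r.registrations
                nox_tot[cell] = nox_tot.get(cell, 0.0) + annual_model_nox(
                    r.nox_rde, r.registrations, d)

        def _nox_mean(cells: Iterable[tuple[str, str]]) -> float | None:
            reg = sum(nox_reg.get(c, 0.0) for c in cells)
            if reg <= 0:
                return None
            return sum(nox_tot.get(c, 0.0) for c in cells) * 1000.0 / reg

        ice_cells = [c for c in counts if c[1] != "bev"]
        fleet_nox = _nox_mean(ice_cells) or 0.0
        co2_rate: dict[tuple[str, str], float] = {}
        nox_rate: dict[tuple[str, str], float] = {}
        for cell, n in counts.items():
            seg, fuel = cell
            if fuel == "bev":
                co2_rate[cell] = 0.0
                nox_rate[cell] = 0.0
                continue
            co2_rate[cell] = co2_tot[cell] / n if n else 0.0
            mean = _nox_mean([cell])
            if mean is None:
                mean = _nox_mean([c for c in ice_cells if c[0] == seg])
            nox_rate[cell] = fleet_nox if mean is None else mean

        phev_cells = [c for c in counts if c[1] == "petrol_phev"]
        phev_n = sum(counts[c] for c in phev_cells)
        if phev_n > 0:
            phev_co2 = sum(co2_tot[c] for c in phev_cells) / phev_n
            phev_nox = _nox_mean(phev_cells)
            phev_nox = fleet_nox if phev_nox is None else phev_nox
        else:  # no PHEVs in the input fleet: fall back to petrol rates
            pet = [c for c in counts if c[1] == "petrol"]
            pet_n = sum(counts[c] for c in pet)
            phev_co2 = sum(co2_tot[c] for c in pet) / pet_n if pet_n else 0.0
            phev_nox = _nox_mean(pet) or fleet_nox
        return cls(counts, co2_rate, nox_rate, phev_co2, phev_nox)

    @property
    def total_registrations(self) -> float:
        return sum(self.counts.values())

    @property
    def base_bev_share(self) -> float:
        bev = sum(n for (s, f), n in self.counts.items() if f == "bev")
        return bev / self.total_registrations

    def segments(self) -> list[str]:
        return sorted({s for s, _ in self.counts})

    def co2_rate_for(self, segment: str, fuel: str) -> float:
        if fuel == "bev":
            return 0.0
        if fuel == "petrol_phev" and (segment, fuel) not in self.co2_rate:
            return self.phev_co2_rate
        try:
            return self.co2_rate[(segment, fuel)]
        except KeyError:
            raise KeyError(f"no CO2 rate for segment {segment!r}, fuel {fuel!r}") from None

    def nox_rate_for(self, segment: str, fuel: str) -> float:
        if fuel == "bev":
            return 0.0
        if fuel == "petrol_phev" and (segment, fuel) not in self.nox_rate:
            return self.phev_nox_rate
        try:
            return self.nox_rate[(segment, fuel)]
        except KeyError:
            raise KeyError(f"no NOx rate for segment {segment!r}, fuel {fuel!r}") from None


def bev_share(spec: ScenarioSpec, year: int, base_share: float = 0.047) -> float:
    """Battery-electric share of new sales in a given calendar year.

    Non-electrified scenarios hold the 2020 share constant.  Electrified
    scenarios interpolate linearly from the 2020 share through the anchor
    years and saturate at 1.0 after the last anchor.
    """
    if year < POLICY_START:
        raise ValueError(f"year must be >= {POLICY_START}")
    if not spec.electrified:
        return base_share
    years = [POLICY_START] + sorted(spec.bev_anchors)
    shares = [base_share] + [spec.bev_anchors[y] for y in sorted(spec.bev_anchors)]
    if year >= years[-1]:
        return shares[-1]
    return float(np.interp(year, years, shares))


def _substitute(counts: dict[tuple[str, str], float],
                substitutions: Mapping[str, str],
                profiles: CohortProfiles) -> dict[tuple[str, str], float]:
    """Move source-segment sales to the target segment's own fuel mix."""
    out = {c: n for c, n in counts.items() if c[0] not in substitutions}
    for src, tgt in substitutions.items():
        moved = sum(n for (s, f), n in counts.items() if s == src)
        if moved == 0:
            continue
        tgt_cells = {c: n for c, n in profiles.counts.items() if c[0] == tgt}
        if not tgt_cells:
            raise KeyError(
                f"substitution target segment {tgt!r} absent from base profiles")
        tgt_total = sum(tgt_cells.values())
        for (s, f), n in tgt_cells.items():
            out[(s, f)] = out.get((s, f), 0.0) + moved * n / tgt_total
    return out


def _electrify(counts: dict[tuple[str, str], float], share: float, year: int,
               phev_rule: bool) -> dict[tuple[str, str], float]:
    """Apply a uniform BEV share per segment; split the residual by 2020 mix."""
    segments: dict[str, dict[str, float]] = {}
    for (s, f), n in counts.items():
        segments.setdefault(s, {})[f] = n
    out: dict[tuple[str, str], float] = {}
    for seg, mix in segments.items():
        total = sum(mix.values())
        if total == 0:
            continue
        out[(seg, "bev")] = out.get((seg, "bev"), 0.0) + total * share
        residual = total * (1.0 - share)
        if residual <= 0:
            continue
        if phev_rule and PHEV_FROM <= year <= PHEV_UNTIL:
            out[(seg, "petrol_phev")] = out.get((seg, "petrol_phev"), 0.0) + residual
        else:
            ice_mix = {f: n for f, n in mix.items() if f != "bev"}
            ice_total = sum(ice_mix.values())
            if ice_total == 0:  # segment was already fully electric in 2020
                out[(seg, "bev")] += residual
                continue
            for f, n in ice_mix.items():
                out[(seg, f)] = out.get((seg, f), 0.0) + residual * n / ice_total
    return out


def compose_cohort(spec: ScenarioSpec, year: int, profiles: CohortProfiles,
                   sales: SalesTrajectory | None = None,
                   ) -> dict[tuple[str, str], float]:
    """New registrations by (segment key, fuel) for one scenario-year.

    The 2020 base composition is scaled to the year's sales, segment
    substitutions are applied first, then (in electrified scenarios) the BEV
    share uniformly across segments.  Total count equals the sales trajectory
    exactly.
    """
    sales = sales or SalesTrajectory(base_year_sales=profiles.total_registrations)
    total = sales.sales(year)
    base_total = profiles.total_registrations
    counts = {c: n * total / base_total for c, n in profiles.counts.items()}
    counts = _substitute(counts, spec.substitutions, profiles)
    # The policy-start cohort keeps its observed fuel composition: the BEV
    # uptake trajectory starts from the 2020 share, so electrification first
    # alters the mix in the following year.
    if spec.electrified and year > POLICY_START:
        share = bev_share(spec, year, base_share=profiles.base_bev_share)
        counts = _electrify(counts, share, year, spec.phev_rule)
    return counts
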