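"""Vehicle fleet data model, segment classification and annual tailpipe accounting.

A fleet is a collection of :class:`VehicleModelRecord` objects, one per vehicle
model on sale (e.g. "the best-selling Ford Puma variant"), each carrying its
2020 registration count, physical characteristics and type-approval emission
values (WLTP CO2 in g/km, RDE NOx in mg/km).  Annual per-model emissions are
the per-km value times registrations times an assumed annual distance for the
fuel class.  Per-segment averages of those annual values are the building
blocks of every scenario projection downstream.

The SUV market segment (EURO segment J) spans everything from compact
crossovers to heavy off-roaders, so it is sub-classified by kerb mass:
small (<1500 kg), medium (1500-2000 kg, boundaries inclusive) and
large (>2000 kg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EURO_SEGMENTS",
    "FUELS",
    "SEGMENT_KEYS",
    "VehicleModelRecord",
    "DistanceAssumptions",
    "SegmentProfile",
    "classify_segment",
    "annual_model_co2",
    "annual_model_nox",
    "build_segment_profiles",
    "read_fleet",
    "write_fleet",
]

logger = logging.getLogger(__name__)

#: EURO passenger-car market segments (A mini ... F luxury, J SUV, M MPV, S sports).
EURO_SEGMENTS = ("A", "B", "C", "D", "E", "F", "J", "M", "S")

FUELS = ("petrol", "diesel", "petrol_hybrid", "diesel_hybrid", "petrol_phev", "bev")

#: Fuels burning petrol/diesel in any amount (everything except pure battery-electric).
ICE_FUELS = ("petrol", "diesel", "petrol_hybrid", "diesel_hybrid", "petrol_phev")

#: Fuels counted as diesel for the regression indicator and distance assumptions.
DIESEL_FAMILY = ("diesel", "diesel_hybrid")

SMALL_SUV = "small_suv"
MEDIUM_SUV = "medium_suv"
LARGE_SUV = "large_suv"

#: Analysis segment keys: EURO segments with J replaced by its mass sub-classes.
SEGMENT_KEYS = (
    "A", "B", "C", "D", "E", "F",
    SMALL_SUV, MEDIUM_SUV, LARGE_SUV,
    "M", "S",
)

#: Kerb-mass boundaries (kg) of the SUV sub-classes; both boundaries belong to "medium".
SUV_SMALL_BELOW = 1500.0
SUV_LARGE_ABOVE = 2000.0


def classify_segment(segment: str, kerb_mass: float) -> str:
    """Map a EURO segment label to the analysis segment key.

    Non-SUV segments pass through unchanged; segment J is split by kerb mass
    into small (<1500 kg), medium (1500-2000 kg inclusive) and large (>2000 kg)
    SUVs.

    Raises
    ------
    ValueError
        If ``segment`` is not a EURO segment label or ``kerb_mass`` is not
        positive.
    """
    if segment not in EURO_SEGMENTS:
        raise ValueError(f"unknown EURO segment label: {segment!r}")
    if kerb_mass <= 0:
        raise ValueError(f"kerb mass must be positive, got {kerb_mass}")
    if segment != "J":
        return segment
    if kerb_mass < SUV_SMALL_BELOW:
        return SMALL_SUV
    if kerb_mass > SUV_LARGE_ABOVE:
        return LARGE_SUV
    return MEDIUM_SUV


@dataclass(frozen=True)
class VehicleModelRecord:
    """One vehicle model's registrations, characteristics and per-km emissions.

    ``nox_rde`` may be ``None``: some manufacturers had not reported RDE NOx
    at the data cut.  Such records still contribute to CO2 accounting but are
    excluded from NOx averages.
    """

    model_id: str
    registrations: int
    segment: str
    fuel: str
    kerb_mass: float          # kg
    wltp_test_mass: float     # kg
    engine_capacity: float    # cm3, 0 for BEV
    wheelbase: float          # mm
    co2_wltp: float           # g/km, 0 for BEV
    nox_rde: float | None = None  # mg/km, None if unreported

    def __post_init__(self) -> None:
        if self.segment not in EURO_SEGMENTS:
            raise ValueError(f"{self.model_id}: unknown EURO segment {self.segment!r}")
        if self.fuel not in FUELS:
            raise ValueError(f"{self.model_id}: unknown fuel {self.fuel!r}")
        if self.registrations < 0:
            raise ValueError(f"{self.model_id}: negative registrations")
        if self.kerb_mass <= 0 or self.wltp_test_mass <= 0:
            raise ValueError(f"{self.model_id}: masses must be positive")
        if self.wheelbase <= 0:
            raise ValueError(f"{self.model_id}: wheelbase must be positive")
        if self.co2_wltp < 0:
            raise ValueError(f"{self.model_id}: negative CO2")
        if self.nox_rde is not None and self.nox_rde < 0:
            raise ValueError(f"{self.model_id}: negative NOx")
        if self.fuel == "bev":
            if self.co2_wltp != 0 or (self.nox_rde or 0) != 0:
                raise ValueError(f"{self.model_id}: BEV must have zero tailpipe emissions")

    @property
    def segment_key(self) -> str:
        return classify_segment(self.segment, self.kerb_mass)

    @property
    def is_diesel(self) -> bool:
        return self.fuel in DIESEL_FAMILY


@dataclass(frozen=True)
class DistanceAssumptions:
    """Assumed annual distance driven (km/year) by fuel class.

    Defaults are national-travel-survey means: petrol-family 10,137 km,
    diesel-family 15,125 km, and 15,180 km for battery-electric cars.
    Hybrids drive the distance of their base fuel; plug-in hybrids are
    treated as petrol.
    """

    petrol: float = 10_137.0
    diesel: float = 15_125.0
    bev: float = 15_180.0

    def __post_init__(self) -> None:
        if min(self.petrol, self.diesel, self.bev) <= 0:
            raise ValueError("annual distances must be strictly positive")

    def for_fuel(self, fuel: str) -> float:
        if fuel not in FUELS:
            raise ValueError(f"unknown fuel {fuel!r}")
        if fuel == "bev":
            return self.bev
        if fuel in DIESEL_FAMILY:
            return self.diesel
        return self.petrol


def annual_model_co2(c: float, r: float, d: float) -> float:
    """Annual CO2 (tonnes/year) for one model: ``c [g/km] * r * d [km] / 1e6``."""
    if min(c, r, d) < 0:
        raise ValueError("annual_model_co2 inputs must be non-negative")
    return c * r * d / 1e6


def annual_model_nox(n: float, r: float, d: float) -> float:
    """Annual NOx (tonnes/year) for one model: ``n [mg/km] * r * d [km] / 1e9``."""
    if min(n, r, d) < 0:
        raise ValueError("annual_model_nox inputs must be non-negative")
    return n * r * d / 1e9


@dataclass(frozen=True)
class SegmentProfile:
    """Per-segment vehicle count and mean annual per-vehicle emissions.

    ``mean_annual_co2`` is tonnes/vehicle/year over all registrations of the
    segment (battery-electric vehicles included with zero).  ``mean_annual_nox``
    is kg/vehicle/year over the registrations with a reported RDE NOx value
    only (``nox_vehicle_count``).  The registration ratios are the segment's
    share of fleet emissions divided by its share of fleet registrations: a
    value above 1 marks a disproportionately high emitter.
    """

    segment_key: str
    vehicle_count: int
    mean_annual_co2: float        # tonnes/vehicle/year
    mean_annual_nox: float        # kg/vehicle/year
    co2_registration_ratio: float
    nox_registration_ratio: float
    nox_vehicle_count: int = 0

    def __post_init__(self) -> None:
        if self.vehicle_count < 0 or self.nox_vehicle_count < 0:
            raise ValueError("counts must be non-negative")
        for v in (self.mean_annual_co2, self.mean_annual_nox,
                  self.co2_registration_ratio, self.nox_registration_ratio):
            if v < 0:
                raise ValueError("profile values must be non-negative")


def build_segment_profiles(
    records: Iterable[VehicleModelRecord],
    distances: DistanceAssumptions | None = None,
) -> dict[str, SegmentProfile]:
    """Aggregate per-model annual emissions into per-segment profiles.

    Mean annual CO2 per vehicle is total segment annual CO2 divided by the
    segment registration count; the NOx mean divides by the registrations of
    NOx-reporting models only.  Segments with no registrations are omitted
    with a logged warning rather than reported as zero.
    """
    distances = distances or DistanceAssumptions()
    records = list(records)
    if not records:
        raise ValueError("no vehicle records supplied")

    co2_tot: dict[str, float] = {}
    nox_tot: dict[str, float] = {}
    n_reg: dict[str, int] = {}
    n_reg_nox: dict[str, int] = {}
    for rec in records:
        key = rec.segment_key
        d = distances.for_fuel(rec.fuel)
        n_reg[key] = n_reg.get(key, 0) + rec.registrations
        co2_tot[key] = co2_tot.get(key, 0.0) + annual_model_co2(
            rec.co2_wltp, rec.registrations, d)
        if rec.nox_rde is not None:
            n_reg_nox[key] = n_reg_nox.get(key, 0) + rec.registrations
            nox_tot[key] = nox_tot.get(key, 0.0) + annual_model_nox(
                rec.nox_rde, rec.registrations, d)

    fleet_reg = sum(n_reg.values())
    fleet_co2 = sum(co2_tot.values())
    fleet_reg_nox = sum(n_reg_nox.values())
    fleet_nox = sum(nox_tot.values())

    profiles: dict[str, SegmentProfile] = {}
    for key in SEGMENT_KEYS:
        if key not in n_reg:
            continue
        count = n_reg[key]
        if count == 0:
            logger.warning("segment %s has no registrations; omitted from profiles", key)
            continue
        mean_co2 = co2_tot[key] / count
        co2_ratio = ((co2_tot[key] / fleet_co2) / (count / fleet_reg)
                     if fleet_co2 > 0 else 0.0)
        n_nox = n_reg_nox.get(key, 0)
        if n_nox > 0:
            mean_nox = nox_tot[key] * 1000.0 / n_nox  # tonnes -> kg per vehicle
            nox_ratio = ((nox_tot[key] / fleet_nox) / (n_nox / fleet_reg_nox)
                         if fleet_nox > 0 else 0.0)
        else:
            logger.warning("segment %s has no NOx-reporting registrations", key)
            mean_nox = 0.0
            nox_ratio = 0.0
        profiles[key] = SegmentProfile(
            segment_key=key,
            vehicle_count=count,
            mean_annual_co2=mean_co2,
            mean_annual_nox=mean_nox,
            co2_registration_ratio=co2_ratio,
            nox_registration_ratio=nox_ratio,
            nox_vehicle_count=n_nox,
        )
    return profiles


def profiles_frame(profiles: Mapping[str, SegmentProfile]) -> pd.DataFrame:
    """Tabulate segment profiles (one row per segment key)."""
    rows = [
        {
            "segment_key": p.segment_key,
            "vehicle_count": p.vehicle_count,
            "co2_registration_ratio": p.co2_registration_ratio,
            "nox_registration_ratio": p.nox_registration_ratio,
            "co2_tonnes_per_vehicle_year": p.mean_annual_co2,
            "nox_kg_per_vehicle_year": p.mean_annual_nox,
            "nox_vehicle_count": p.nox_vehicle_count,
        }
        for p in profiles.values()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text fleet files
# ---------------------------------------------------------------------------

FLEET_COLUMNS: Sequence[str] = (
    "model_id", "registrations", "segment", "fuel", "kerb_mass",
    "wltp_test_mass", "engine_capacity", "wheelbase", "co2_wltp", "nox_rde",
)


def read_fleet(path: str | Path) -> list[VehicleModelRecord]:
    """Read a fleet CSV (one row per vehicle model, columns ``FLEET_COLUMNS``).

    An empty ``nox_rde`` field means "not reported".  Validation failures
    report the offending data row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in FLEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fleet columns {missing}")
    records: list[VehicleModelRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            nox = getattr(row, "nox_rde")
            records.append(VehicleModelRecord(
                model_id=str(row.model_id),
                registrations=int(row.registrations),
                segment=str(row.segment),
                fuel=str(row.fuel),
                kerb_mass=float(row.kerb_mass),
                wltp_test_mass=float(row.wltp_test_mass),
                engine_capacity=float(row.engine_capacity),
                wheelbase=float(row.wheelbase),
                co2_wltp=float(row.co2_wltp),
                nox_rde=None if pd.isna(nox) else float(nox),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid fleet record at data row {i}: {exc}") from exc
    return records


def write_fleet(records: Iterable[VehicleModelRecord], path: str | Path) -> None:
    """Write records to the fleet CSV schema accepted by :func:`read_fleet`."""
    df = pd.DataFrame([
        {
            "model_id": r.model_id,
            "registrations": r.registrations,
            "segment": r.segment,
            "fuel": r.fuel,
            "kerb_mass": r.kerb_mass,
            "wltp_test_mass": r.wltp_test_mass,
            "engine_capacity": r.engine_capacity,
            "wheelbase": r.wheelbase,
            "co2_wltp": r.co2_wltp,
            "nox_rde": r.nox_rde,
        }
        for r in records
    ], columns=list(FLEET_COLUMNS))
    df.to_csv(path, index=False)
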