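import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suvhealth.fleet import (DistanceAssumptions, VehicleModelRecord,
                             annual_model_co2, annual_model_nox,
                             build_segment_profiles, classify_segment,
                             read_fleet, write_fleet)


class TestClassifySegment:
    @pytest.mark.parametrize("segment, mass, expected", [
        ("J", 2100, "large_suv"),
        ("J", 1400, "small_suv"),
        ("J", 1700, "medium_suv"),
        ("J", 1500, "medium_suv"),   # boundaries belong to medium
        ("J", 2000, "medium_suv"),
        ("J", 1499.9, "small_suv"),
        ("J", 2000.1, "large_suv"),
        ("B", 1200, "B"),
        ("M", 2100, "M"),
    ])
    def test_mass_subclassification(self, segment, mass, expected):
        assert classify_segment(segment, mass) == expected

    def test_unknown_segment_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            classify_segment("X", 1500)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            classify_segment("J", 0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=600, max_value=3500, allow_nan=False))
    def test_every_suv_mass_lands_in_exactly_one_subclass(self, mass):
        key = classify_segment("J", mass)
        assert key in ("small_suv", "medium_suv", "large_suv")


class TestAnnualEmissions:
    @pytest.mark.parametrize("c, r, d, expected", [
        (100, 1, 10_137, 1.0137),
        (170, 10_000, 15_125, 25_712.5),
        (50, 0, 15_125, 0.0),
    ])
    def test_annual_co2_tonnes(self, c, r, d, expected):
        assert annual_model_co2(c, r, d) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n, r, d, expected", [
        (100, 1000, 10_137, 1.0137),
        (80, 100_000, 15_125, 121.0),
        (0, 5000, 10_137, 0.0),
    ])
    def test_annual_nox_tonnes(self, n, r, d, expected):
        assert annual_model_nox(n, r, d) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("fn", [annual_model_co2, annual_model_nox])
    def test_negative_inputs_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-1, 10, 10_000)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 500), st.integers(0, 10**6), st.floats(0, 3))
    def test_scaling_registrations_scales_totals(self, c, r, k):
        base = annual_model_co2(c, r, 10_137)
        assert annual_model_co2(c, k * r, 10_137) == pytest.approx(k * base)


def _rec(model_id="m", registrations=100, segment="B", fuel="petrol",
         kerb=1200.0, engine=1200.0, wheelbase=2500.0, co2=120.0, nox=50.0):
    return VehicleModelRecord(
        model_id=model_id, registrations=registrations, segment=segment,
        fuel=fuel, kerb_mass=kerb, wltp_test_mass=kerb + 100,
        engine_capacity=engine, wheelbase=wheelbase, co2_wltp=co2, nox_rde=nox)


class TestRecordInvariants:
    def test_bev_must_be_zero_emission(self):
        with pytest.raises(ValueError, match="BEV"):
            _rec(fuel="bev", co2=10.0, nox=None)

    def test_negative_registrations_rejected(self):
        with pytest.raises(ValueError):
            _rec(registrations=-1)

    def test_distances_positive_and_by_fuel_family(self, distances):
        assert distances.for_fuel("petrol_phev") == distances.petrol
        assert distances.for_fuel("diesel_hybrid") == distances.diesel
        assert distances.for_fuel("bev") == 15_180.0
        with pytest.raises(ValueError):
            DistanceAssumptions(petrol=0)


class TestSegmentProfiles:
    def test_single_record_segment_mean_is_that_record(self, distances):
        recs = [_rec(model_id="a", segment="A", registrations=10, co2=100.0),
                _rec(model_id="b", segment="B", registrations=5, co2=200.0)]
        profs = build_segment_profiles(recs, distances)
        expect = annual_model_co2(100.0, 10, distances.petrol) / 10
        assert profs["A"].mean_annual_co2 == pytest.approx(expect)

    def test_grouped_totals_conserve_fleet_total(self, fleet, distances):
        profs = build_segment_profiles(fleet, distances)
        total_by_segments = sum(p.mean_annual_co2 * p.vehicle_count
                                for p in profs.values())
        total_by_records = sum(
            annual_model_co2(r.co2_wltp, r.registrations, distances.for_fuel(r.fuel))
            for r in fleet)
        assert total_by_segments == pytest.approx(total_by_records, rel=1e-12)

    def test_registration_scaling_leaves_means_unchanged(self, fleet, distances):
        profs = build_segment_profiles(fleet, distances)
        scaled = [VehicleModelRecord(
            model_id=r.model_id, registrations=3 * r.registrations,
            segment=r.segment, fuel=r.fuel, kerb_mass=r.kerb_mass,
            wltp_test_mass=r.wltp_test_mass, engine_capacity=r.engine_capacity,
            wheelbase=r.wheelbase, co2_wltp=r.co2_wltp, nox_rde=r.nox_rde)
            for r in fleet]
        profs3 = build_segment_profiles(scaled, distances)
        for key, p in profs.items():
            assert profs3[key].vehicle_count == 3 * p.vehicle_count
            assert profs3[key].mean_annual_co2 == pytest.approx(p.mean_annual_co2)

    def test_fleet_wide_ratio_normalisation(self, fleet, distances):
        """Registration-share-weighted emission ratios sum to one by construction."""
        profs = build_segment_profiles(fleet, distances)
        fleet_reg = sum(p.vehicle_count for p in profs.values())
        acc = sum(p.co2_registration_ratio * p.vehicle_count / fleet_reg
                  for p in profs.values())
        assert acc == pytest.approx(1.0, rel=1e-12)

    def test_suv_subclasses_partition_segment_j(self, fleet):
        n_j = sum(r.registrations for r in fleet if r.segment == "J")
        n_parts = sum(r.registrations for r in fleet
                      if r.segment_key in ("small_suv", "medium_suv", "large_suv"))
        assert n_parts == n_j

    def test_records_without_nox_kept_for_co2_only(self, distances):
        recs = [_rec(model_id="a", registrations=10, co2=100.0, nox=None),
                _rec(model_id="b", registrations=10, co2=100.0, nox=80.0)]
        p = build_segment_profiles(recs, distances)["B"]
        assert p.vehicle_count == 20
        assert p.nox_vehicle_count == 10
        expect_nox = annual_model_nox(80.0, 10, distances.petrol) * 1000 / 10
        assert p.mean_annual_nox == pytest.approx(expect_nox)

    def test_empty_fleet_rejected(self):
        with pytest.raises(ValueError):
            build_segment_profiles([])


class TestFleetIO:
    def test_roundtrip(self, fleet, tmp_path):
        path = tmp_path / "fleet.csv"
        write_fleet(fleet, path)
        back = read_fleet(path)
        assert len(back) == len(fleet)
        for a, b in zip(back, fleet):
            assert (a.model_id, a.registrations, a.segment, a.fuel) == \
                   (b.model_id, b.registrations, b.segment, b.fuel)
            assert a.co2_wltp == pytest.approx(b.co2_wltp, rel=1e-12)
            if b.nox_rde is None:
                assert a.nox_rde is None
            else:
                assert a.nox_rde == pytest.approx(b.nox_rde, rel=1e-12)

    def test_invalid_row_number_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "model_id,registrations,segment,fuel,kerb_mass,wltp_test_mass,"
            "engine_capacity,wheelbase,co2_wltp,nox_rde\n"
            "ok,10,B,petrol,1200,1300,1200,2500,120,50\n"
            "bad,10,Q,petrol,1200,1300,1200,2500,120,50\n")
        with pytest.raises(ValueError, match="row 2"):
            read_fleet(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("model_id,registrations\nx,1\n")
        with pytest.raises(ValueError, match="missing"):
            read_fleet(path)
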