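import pytest

from suvhealth.fleet import DistanceAssumptions
from suvhealth.scenarios import CohortProfiles
from suvhealth.synth import FleetGenConfig, generate_fleet, generate_population
from suvhealth.turnover import calibrate_survival


@pytest.fixture(scope="session")
def fleet():
    """Default synthetic fleet, one fixed seed for the whole suite."""
    return generate_fleet(FleetGenConfig(seed=1))


@pytest.fixture(scope="session")
def distances():
    return DistanceAssumptions()


@pytest.fixture(scope="session")
def cohort_profiles(fleet, distances):
    return CohortProfiles.from_records(fleet, distances)


@pytest.fixture(scope="session")
def calibration():
    return calibrate_survival()


@pytest.fixture(scope="session")
def schedule(calibration):
    return calibration.schedule


@pytest.fixture(scope="session")
def population():
    return generate_population()
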