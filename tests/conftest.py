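import pytest

import rtcost as rc
from rtcost.costing import load_calibration_table


@pytest.fixture(scope="session")
def registry():
    return rc.default_registry()


@pytest.fixture(scope="session")
def slot_table():
    return rc.default_slot_table()


@pytest.fixture(scope="session")
def staff_rates():
    return rc.default_staff_rates()


@pytest.fixture(scope="session")
def params():
    return rc.CostParameters()


@pytest.fixture(scope="session")
def profiles(registry, params):
    return rc.load_profiles(registry, params)


@pytest.fixture(scope="session")
def calibration():
    return load_calibration_table()


@pytest.fixture(scope="session")
def spec():
    return rc.load_cohort_spec()


@pytest.fixture(scope="session")
def cohort(spec, registry):
    patients, report = rc.generate_cohort(spec, registry)
    assert report.ok
    return patients


@pytest.fixture(scope="session")
def trajectory(cohort, profiles, registry):
    return rc.run_scenario(cohort, rc.get_changes(), profiles, registry)


@pytest.fixture(scope="session")
def verbatim_26_5(registry):
    paths = rc.default_carepaths()
    return paths["26-5"]
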