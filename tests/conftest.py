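import pytest

from careproj import baseline_scenario, project


@pytest.fixture(scope="session")
def diagnosis_scenario():
    return baseline_scenario("diagnosis")


@pytest.fixture(scope="session")
def treatment_scenario():
    return baseline_scenario("treatment")


@pytest.fixture(scope="session")
def diagnosis_table(diagnosis_scenario):
    return project(diagnosis_scenario)


@pytest.fixture(scope="session")
def treatment_table(treatment_scenario):
    return project(treatment_scenario)
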