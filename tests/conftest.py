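import pytest

import esocea as e


@pytest.fixture(scope="session")
def stage1():
    return e.load_fixture("stage1_base")


@pytest.fixture(scope="session")
def stage23():
    return e.load_fixture("stage23_base")


@pytest.fixture(scope="session")
def totals():
    return e.load_fixture("basecase_totals")


@pytest.fixture(scope="session")
def ranges():
    return e.load_fixture("ranges")


@pytest.fixture(scope="session")
def stage1_calibrated(stage1, totals):
    return e.calibrate_parameter_set(stage1, totals["I"])


@pytest.fixture(scope="session")
def stage23_calibrated(stage23, totals):
    return e.calibrate_parameter_set(stage23, totals["II_III"])


@pytest.fixture(scope="session")
def all_strategies(stage1, stage23):
    """All six bundled parameter sets (five interventions; esophagectomy
    appears in both stage groups)."""
    return list(stage1) + list(stage23)


@pytest.fixture(scope="session")
def settings(stage1):
    return stage1.settings
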