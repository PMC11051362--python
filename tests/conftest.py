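import pytest

from sfrtsim import case_report_scenario, default_lq_parameters, fractionated_schedule


@pytest.fixture(scope="session")
def calibrated_lq():
    """The package-default (alpha, beta) calibrated from the fixture factors."""
    return default_lq_parameters()


@pytest.fixture(scope="session")
def palliative_schedule():
    """10 daily whole-tumor fractions of 3 Gy, days 1..10."""
    return fractionated_schedule(dose_gy=3.0, n_fractions=10, first_day=1.0)


@pytest.fixture()
def fixture_scenario():
    """The built-in clinical scenario (fresh copy per test)."""
    return case_report_scenario()
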