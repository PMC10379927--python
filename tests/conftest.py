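import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from anacquant.calibration import CalibrationLevel, calibrate
from anacquant.catalog import default_catalog

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRINTED_SLOPE = 2333.5
PRINTED_INTERCEPT = 2956.2
PRINTED_LEVELS = (1.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@pytest.fixture(scope="session")
def printed_line_levels():
    """Triplicate areas lying exactly on the published calibration line."""
    return [
        CalibrationLevel(x, (PRINTED_SLOPE * x + PRINTED_INTERCEPT,) * 3)
        for x in PRINTED_LEVELS
    ]


@pytest.fixture(scope="session")
def printed_line_fit(printed_line_levels):
    return calibrate(printed_line_levels)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()
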