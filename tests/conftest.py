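import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardioresp.protocol import ManeuverProtocol, Phase
from cardioresp.simulate import generate_cohort, make_preset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    """Calibrated presets for all four HRR types (calibration runs once, cached)."""
    return {label: make_preset(label) for label in ("I", "II", "III", "IV")}


@pytest.fixture(scope="session")
def sr_protocol():
    """A single 2-minute spontaneous-breathing phase."""
    return ManeuverProtocol((Phase("SR", 120.0),))


@pytest.fixture(scope="session")
def default_cohort():
    """The published-size cohort (53/29/85/16) at a fixed master seed."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def cohort_frames(default_cohort):
    from cardioresp.pipeline import analyze_cohort

    return analyze_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
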