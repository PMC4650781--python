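import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from braggmap.physics import BeamSpec, column_conditions, default_jig

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def beam():
    """Calibrated default beam (79.7 MeV nominal, 4.8 cm water range)."""
    return BeamSpec()


@pytest.fixture(scope="session")
def jig(beam):
    return default_jig(beam)


@pytest.fixture(scope="session")
def conditions(beam, jig):
    return column_conditions(beam, jig)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
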