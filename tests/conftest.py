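import numpy as np
import pytest

from hes7clock import WILD_TYPE, integrate, trajectory_metrics


@pytest.fixture(scope="session")
def wild_type_trajectory():
    """Calibrated wild-type run shared across tests (deterministic)."""
    return integrate(WILD_TYPE, t_end=2400.0, dt=0.05)


@pytest.fixture(scope="session")
def wild_type_metrics(wild_type_trajectory):
    return trajectory_metrics(wild_type_trajectory, channel="mrna")


@pytest.fixture
def sinusoid_120():
    """Pure 120-min sinusoid sampled at dt = 0.05 over 1200 min."""
    t = np.arange(0.0, 1200.0 + 1e-9, 0.05)
    return t, np.sin(2.0 * np.pi * t / 120.0)
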