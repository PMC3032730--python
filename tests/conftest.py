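import numpy as np
import pytest

from mpflim import DEFAULT_TIME_AXIS, TimeAxis
from mpflim.simulator import analytic_reference


@pytest.fixture(scope="session")
def axis_small() -> TimeAxis:
    """Short 256-channel axis (~12.5 ns) for fast unit tests."""
    return TimeAxis(256, 48.8)


@pytest.fixture(scope="session")
def axis_default() -> TimeAxis:
    return DEFAULT_TIME_AXIS


@pytest.fixture(scope="session")
def ref_small(axis_small):
    """Noise-free 86 ps reference with a 150 ps Gaussian response."""
    return analytic_reference(86.0, 150.0, 2440.0, axis_small)


@pytest.fixture(scope="session")
def ref_default(axis_default):
    return analytic_reference(86.0, 150.0, 2440.0, axis_default)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
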