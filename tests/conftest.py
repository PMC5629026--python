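import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from earshot import ArrayGeometry, FilterbankSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 48000.0


@pytest.fixture(scope="session")
def geometry():
    """The standard array: 0.145 m spacing, 343 m/s, 48 kHz."""
    return ArrayGeometry()


@pytest.fixture(scope="session")
def filterbank():
    """The standard 50-band linear 100-5000 Hz gammatone layout."""
    return FilterbankSpec()


@pytest.fixture(scope="session")
def small_filterbank():
    """A light 10-band layout for tests that exercise the whole pipeline."""
    return FilterbankSpec(n_bands=10, f_low_hz=300.0, f_high_hz=3000.0)


def gaussian_bump(centre_deg: float, width_deg: float = 5.0, floor: float = 1e-6):
    """Circular Gaussian bump on the 360-degree grid (test-building helper)."""
    grid = np.arange(360.0)
    d = np.minimum(np.abs(grid - centre_deg), 360.0 - np.abs(grid - centre_deg))
    return floor + np.exp(-0.5 * (d / width_deg) ** 2)
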