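import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popwaves import radiocarbon, spd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def identity_curve():
    """Identity calendar→¹⁴C mapping with near-zero curve error."""
    cal = np.arange(-100.0, 3001.0)
    return radiocarbon.CalibrationCurve(cal, cal.copy(), np.full(cal.size, 1e-6), name="identity")


@pytest.fixture
def flat_sigma_curve():
    """Identity mapping with a constant 10-yr curve error (for symmetry tests)."""
    cal = np.arange(-100.0, 3001.0)
    return radiocarbon.CalibrationCurve(cal, cal.copy(), np.full(cal.size, 10.0), name="flat10")


def make_generations(values, width=30, oldest=3000):
    """GenerationalSeries from forward-in-time values."""
    values = np.asarray(values, dtype=float)
    starts = oldest - width * np.arange(values.size)
    return spd.GenerationalSeries(starts, values, bin_width=width)


@pytest.fixture
def gen_factory():
    return make_generations
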