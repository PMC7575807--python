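import numpy as np
import pytest

from sadjerk import UniformSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hr_like(rng):
    """A heart-rate-like series: slow drift plus noise, 600 s at 1 Hz."""
    t = np.arange(600.0)
    v = 100 + 15 * np.sin(t / 120) + rng.normal(0, 2, t.size)
    return UniformSeries(v)


def make_random_series(rng, n=200, base=100.0, drift=10.0, noise=5.0):
    t = np.arange(float(n))
    v = base + drift * np.sin(t / (n / 4)) + rng.normal(0, noise, n)
    return UniformSeries(v)
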