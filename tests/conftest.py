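import numpy as np
import pytest

from elemdyn.series import BiomarkerSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid():
    """Noiseless sinusoid, 40 samples per period, 10 periods."""
    t = np.arange(400)
    return BiomarkerSeries(time=t * 0.02, values=np.sin(2 * np.pi * t / 40))


@pytest.fixture
def white_noise(rng):
    return BiomarkerSeries(time=np.arange(400) * 0.02, values=rng.standard_normal(400))


def make_series(values):
    values = np.asarray(values, dtype=float)
    return BiomarkerSeries(time=np.arange(values.size, dtype=float), values=values)
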