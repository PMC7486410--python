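import numpy as np
import pytest

from cahub import ActivityRaster, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poisson_raster():
    """Independent Poisson raster: 40 cells, 60 s at 10 Hz, 0.5 Hz/cell."""
    g = np.random.default_rng(7)
    onsets = (g.random((40, 600)) < 0.05).astype(np.uint8)
    return ActivityRaster(onsets, 10.0)


@pytest.fixture
def full_rest():
    def make(n_frames):
        return EpochSet("rest", [[0, n_frames]])
    return make
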