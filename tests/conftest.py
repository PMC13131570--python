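import numpy as np
import pytest

from engramnet import EventRaster, RegistrationMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_raster(rng, T=None, N=None, density=0.05, frame_period=0.1, session_id="other"):
    T = T if T is not None else int(rng.integers(12, 200))
    N = N if N is not None else int(rng.integers(1, 10))
    counts = (rng.random((T, N)) < density).astype(np.int64)
    counts += (rng.random((T, N)) < density / 4).astype(np.int64)  # occasional counts of 2
    return EventRaster(counts, frame_period=frame_period, session_id=session_id)


@pytest.fixture
def small_raster():
    counts = np.zeros((30, 3), dtype=int)
    counts[5, 0] = 1
    counts[5, 1] = 1
    counts[20, 2] = 2
    return EventRaster(counts, neuron_ids=["a", "b", "c"], session_id="training")


@pytest.fixture
def identity_map():
    def make(ids, sessions):
        return RegistrationMap.identity(ids, sessions)

    return make
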