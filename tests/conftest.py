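import numpy as np
import pytest
from hypothesis import settings

from devmea.io import ArrayGeometry, SpikeTrainSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_geom() -> ArrayGeometry:
    return ArrayGeometry(8, 8)


@pytest.fixture
def single_geom() -> ArrayGeometry:
    return ArrayGeometry(1, 1)


def make_spikes(geom, duration, trains, amplitude=-50.0):
    """Build a SpikeTrainSet from {electrode: times} with a flat amplitude."""
    times = {e: np.asarray(t, dtype=float) for e, t in trains.items()}
    amps = {e: np.full(len(t), amplitude) for e, t in trains.items()}
    return SpikeTrainSet(geom, duration, times, amps)
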