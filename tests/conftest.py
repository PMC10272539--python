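import numpy as np
import pytest

from cardiospinal import ProtocolTimeline, SpikeTrain, SpikeTrainSet


@pytest.fixture
def timeline() -> ProtocolTimeline:
    """Compact protocol: 2 min baseline with stimulation + stimulus epochs,
    3 min occlusions, reperfusions, a stimulation period, 1 min post baseline."""
    epochs = {
        "baseline_pre": (0.0, 120.0),
        "lad_pre": (120.0, 300.0),
        "rep_pre": (300.0, 420.0),
        "scs": (420.0, 540.0),
        "baseline_post": (540.0, 600.0),
        "lad_post": (600.0, 780.0),
        "rep_post": (780.0, 900.0),
        "touch_rv": (10.0, 25.0),
        "bradykinin": (40.0, 55.0),
    }
    pulses = 60.0 + np.arange(30.0)
    return ProtocolTimeline(epochs, {"t2": pulses})


@pytest.fixture
def line_adjacency():
    """Five electrodes in a line: 0-1-2-3-4."""
    return {0: {1}, 1: {0, 2}, 2: {1, 3}, 3: {2, 4}, 4: {3}}


def make_set(trains_spec, adjacency, duration):
    """Build a SpikeTrainSet from [(neuron_id, electrode, times), ...]."""
    trains = [
        SpikeTrain(nid, e, np.asarray(t, dtype=float)) for nid, e, t in trains_spec
    ]
    return SpikeTrainSet(trains, adjacency, duration)


@pytest.fixture
def make_trainset(line_adjacency):
    def _make(trains_spec, duration=10.0, adjacency=None):
        return make_set(trains_spec, adjacency or line_adjacency, duration)

    return _make
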