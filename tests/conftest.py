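import numpy as np
import pytest

from getfret.bursts import dual_channel_burst_search, estimate_background, filter_bursts
from getfret.photons import PhotonStream
from getfret.simulate import simulate_photon_stream, three_state_config


@pytest.fixture(scope="session")
def dynamic_stream():
    """60 s three-state acquisition: ms open/closed dynamics + blinking."""
    cfg = three_state_config(100.0, 200.0, duration=60.0, seed=101)
    return simulate_photon_stream(cfg)


@pytest.fixture(scope="session")
def dynamic_background(dynamic_stream):
    return estimate_background(dynamic_stream)


@pytest.fixture(scope="session")
def dynamic_bursts(dynamic_stream, dynamic_background):
    return filter_bursts(
        dual_channel_burst_search(dynamic_stream, background=dynamic_background)
    )


def build_stream(ticks, streams, clock=100e-9, duration=None):
    """Hand-build a PhotonStream from tick/stream-code arrays (DD=0,DA=1,AA=2)."""
    ticks = np.asarray(ticks, np.int64)
    streams = np.asarray(streams)
    detector = np.where(streams == 0, 0, 1).astype(np.int8)
    excitation = np.where(streams == 2, 1, 0).astype(np.int8)
    if duration is None:
        duration = float((ticks[-1] + 1) * clock) if ticks.size else 0.0
    return PhotonStream(ticks, detector, excitation, clock, duration)
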