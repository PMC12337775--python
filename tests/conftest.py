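import numpy as np
import pytest

from vasodyn.geometry import Segment, VesselNetwork
from vasodyn.synthgen import GroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_segment():
    pts = np.column_stack([np.linspace(50.0, 2050.0, 41), np.full(41, 100.0)])
    return Segment(points=pts, d0=25.0, cls="artery")


@pytest.fixture
def straight_network(straight_segment):
    return VesselNetwork(segments=[straight_segment], source=(50.0, 100.0),
                         field_size=(2100.0, 200.0))


@pytest.fixture
def default_truth():
    return GroundTruth(v=4.13, lam=1600.0, a0=0.08, d_rise=0.25, t0=3.0,
                       duration=2.0, noise_sd=0.0, seed=0)
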