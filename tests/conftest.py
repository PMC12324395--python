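import numpy as np
import pytest

from gridshift.containers import TrackLayout
from gridshift.synth import default_layout


@pytest.fixture
def layout():
    return default_layout()


@pytest.fixture
def layout_1cm():
    return default_layout(bin_size_cm=1.0)


@pytest.fixture
def small_layout():
    return TrackLayout(length_cm=100.0, landmark_edges_cm=(30.0, 70.0), bin_size_cm=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
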