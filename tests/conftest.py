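import numpy as np
import pytest

from microtrauma.netmetrics import SpikeTrainSet


@pytest.fixture
def periodic_trains():
    """20 identical periodic trains (period 2 s over 60 s)."""
    t = np.arange(1.0, 59.0, 2.0)
    return SpikeTrainSet(trains=[t.copy() for _ in range(20)], duration=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
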