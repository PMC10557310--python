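import numpy as np
import pytest

from squigq import signal_io as sio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_feature_spec():
    """Noiseless continuous trace: every feature segment is exactly n=4 long."""
    kinds = ["increase", "peak", "decrease", "valley", "increase", "valley",
             "decrease", "peak"]
    segs = sio.continuous_plan(kinds, const_len=20, feat_len=4, level=450, slope=10)
    return sio.SyntheticSpec(segs, noise_sd=0.0, seed=1)


@pytest.fixture
def small_code_spec():
    """Noiseless trace on a 5-bit code alphabet for the quantum scanner."""
    kinds = ["increase", "peak", "decrease", "valley"]
    segs = sio.continuous_plan(kinds, const_len=8, feat_len=4, level=12, slope=3)
    return sio.SyntheticSpec(segs, noise_sd=0.0, seed=3, value_range=(0, 31))
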