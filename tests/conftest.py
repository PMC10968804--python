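import numpy as np
import pytest

from sleepwvd.features import FeatureSeries
from sleepwvd.signal_io import EPOCH_LEN_S


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_features(n_epochs: int, pm=None, pw=None, pn3=None) -> FeatureSeries:
    """FeatureSeries with given per-second vectors (zeros by default)."""
    n = n_epochs * EPOCH_LEN_S
    z = np.zeros(n)
    return FeatureSeries(
        pm=z if pm is None else np.asarray(pm, float),
        pw=z if pw is None else np.asarray(pw, float),
        pn3=z if pn3 is None else np.asarray(pn3, float),
    )
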