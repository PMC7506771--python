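import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_ecg():
    """A short zero-noise ECG with exactly four beats 1 s apart."""
    from rehabsig import synth

    sig, truth = synth.gen_ecg([1000.0, 1000.0, 1000.0], fs=500.0)
    return sig, truth
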