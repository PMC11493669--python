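import numpy as np
import pytest

from ecgcs import EcgSynthParams, synth_ecg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_ecg():
    """A 512-sample quasi-periodic test signal (default generator settings)."""
    return synth_ecg(EcgSynthParams(duration_s=512.0 / 360.0, seed=7))
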