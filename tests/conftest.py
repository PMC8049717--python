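import numpy as np
import pytest

from songphen.synthgen import SynthConfig
from songphen.types import MotifWaveform


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_synth_config():
    """A fast, small motif-family configuration used across tests."""
    return SynthConfig(
        n_birds=3, renditions_per_context=6, rate_hz=22050.0, seed=11
    )


@pytest.fixture()
def sine_motif():
    rate = 22050.0
    t = np.arange(int(0.5 * rate)) / rate
    return MotifWaveform(np.sin(2 * np.pi * 1000.0 * t), rate, "sine", "courtship")


@pytest.fixture()
def noise_motif(rng):
    rate = 22050.0
    return MotifWaveform(rng.normal(size=int(0.5 * rate)), rate, "noise", "courtship")
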