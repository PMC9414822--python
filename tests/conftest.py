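import numpy as np
import pytest

from adrofit import (
    Calibration,
    Waveform,
    decompose,
    frame_spl,
    load_table1_profiles,
    mix_at_snr,
    synthesize_babble,
    synthesize_utterance,
)


@pytest.fixture(scope="session")
def profiles():
    """The ten published subject profiles."""
    return load_table1_profiles()


@pytest.fixture(scope="session")
def profile(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def mixture():
    """A standard 2.5 s training stimulus: utterance + babble at 5 dB SNR."""
    utt = synthesize_utterance(2.5, seed=1)
    babble = synthesize_babble(8, 2.5, seed=2)
    return mix_at_snr(utt, babble, 5.0)


@pytest.fixture(scope="session")
def noise_30s():
    """Stationary Gaussian noise, 30 s, used for equilibrium studies."""
    rng = np.random.default_rng(42)
    return Waveform(0.05 * rng.standard_normal(16000 * 30))


@pytest.fixture(scope="session")
def noise_levels(noise_30s):
    """Per-frame band SPL of the stationary noise under default calibration."""
    bf = decompose(noise_30s)
    return frame_spl(bf, Calibration()), bf.frame_hop_s
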