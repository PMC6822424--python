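import numpy as np
import pytest

from sqsleep import Recording, SynthConfig, make_study

FS = 207.0
EPOCH_S = 30.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sinusoid_epoch(freq_hz: float, fs: float = FS, dur_s: float = EPOCH_S,
                   amp: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(dur_s * fs))) / fs
    return amp * np.cos(2 * np.pi * freq_hz * t)


@pytest.fixture
def noise_recording(rng) -> Recording:
    """Two-channel 90-s white-noise recording at 207 Hz."""
    sig = rng.normal(0.0, 20.0, size=(2, int(90 * FS)))
    return Recording(signal=sig, fs=FS, channel_names=("P-C", "D-C"))


@pytest.fixture(scope="session")
def tiny_study():
    """Two patients x two nights x 20 epochs — fast but complete."""
    cfg = SynthConfig(
        n_patients=2, nights_per_patient=(2, 2), epochs_per_night=20, seed=7
    )
    return cfg, make_study(cfg)
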