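import numpy as np
import pytest

from systoseg import BeatTrainSpec, SampledSignal, generate_beat_train


@pytest.fixture(scope="session")
def default_train():
    """The default study profile: 28 beats / ~20 s at 2 kHz, SNR 20 dB."""
    return generate_beat_train(BeatTrainSpec(seed=0))


@pytest.fixture(scope="session")
def clean_train():
    """Noiseless, jitter-free beat train for exact fiducial checks."""
    spec = BeatTrainSpec(seed=0, noise_snr_db=np.inf, rr_jitter_ms=0.0,
                         interval_jitter_ms=0.0)
    return generate_beat_train(spec)


def make_signal(samples, fs=1000.0, t0=0.0):
    return SampledSignal(np.asarray(samples, dtype=float), fs, t0)


@pytest.fixture
def gaussian_burst():
    """One symmetric burst centred at 1.0 s in 3 s of faint noise."""
    fs = 1000.0
    t = np.arange(int(3 * fs)) / fs
    rng = np.random.default_rng(42)
    x = np.exp(-0.5 * ((t - 1.0) / 0.01) ** 2) + 1e-4 * rng.normal(size=t.size)
    return SampledSignal(x, fs)
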