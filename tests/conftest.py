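import numpy as np
import pytest

from gswnet import preprocess, syndata


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject cohort at default study conditions (cached per session)."""
    cfg = syndata.SynthConfig(n_subjects=3, seed=11)
    recordings, truths, lead_field = syndata.synthesize_cohort(cfg)
    return cfg, recordings, truths, lead_field


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def sine_recording():
    """19-channel recording carrying a pure 10 Hz sine on every channel."""
    fs = 256.0
    t = np.arange(int(10 * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * 10.0 * t), (19, 1))
    data *= np.linspace(0.5, 1.5, 19)[:, None]
    return preprocess.SensorRecording(data, fs, list(preprocess.CHANNELS_1020))
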