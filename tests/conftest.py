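import numpy as np
import pytest

from pacorrect.events import EEGRecording, RPeakSeries
from pacorrect.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured synthetic configuration (fast to generate)."""
    return SyntheticConfig(
        n_channels=16,
        duration=90.0,
        seed=7,
        alpha_channels=("O1", "Oz", "O2"),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(data, fs=250.0, labels=None, stage="raw"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"C{2 * i + 1}" for i in range(data.shape[0])]
    return EEGRecording(data=data, fs=fs, labels=labels, stage=stage)


def periodic_rpeaks(n_samples, fs=250.0, rr_s=1.0, t0_s=0.5):
    idx = np.arange(int(t0_s * fs), n_samples, int(rr_s * fs))
    return RPeakSeries(indices=idx, fs=fs)
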