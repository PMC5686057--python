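import numpy as np
import pytest

from mobiqc import Recording, load_headset_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def m4s():
    return load_headset_profile("M4S")


@pytest.fixture
def ss():
    return load_headset_profile("SS")


def make_recording(signal, fs=256.0, labels=None, subject="t", headset="SS"):
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if labels is None:
        labels = tuple(f"C{i}" for i in range(signal.shape[0]))
    return Recording(subject_id=subject, headset=headset, signal=signal,
                     sampling_rate=fs, channel_labels=tuple(labels))


@pytest.fixture
def noise_recording(rng):
    """4-channel, 60 s, 256 Hz white-noise recording at 10 uV RMS."""
    fs = 256.0
    return make_recording(rng.standard_normal((4, int(fs * 60))) * 10.0,
                          fs=fs, labels=("F3", "F4", "P3", "P4"))
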