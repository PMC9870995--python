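import numpy as np
import pytest

from eegmacro.montage import BIOSEMI64_LABELS, standard_positions
from eegmacro.preprocess import CANONICAL_BANDS, EpochSet, Recording

BANDS = {b.name: b for b in CANONICAL_BANDS}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alpha_band():
    return BANDS["alpha"]


@pytest.fixture
def montage64():
    return list(BIOSEMI64_LABELS), standard_positions()


def make_recording(signals, fs=256.0, positions=None):
    signals = np.asarray(signals, dtype=float)
    labels = [f"CH{k:02d}" for k in range(signals.shape[0])]
    return Recording(signals=np.asarray(signals, dtype=float), sample_rate=fs,
                     channel_labels=labels, positions=positions)


def sinusoid_epochs(freqs_per_channel, n_epochs=3, epoch_length=4.0, fs=256.0,
                    phases=None, amplitudes=None, band=None):
    """Epoch set of pure sinusoids, one frequency per channel."""
    n_ch = len(freqs_per_channel)
    phases = phases if phases is not None else [0.0] * n_ch
    amplitudes = amplitudes if amplitudes is not None else [1.0] * n_ch
    n = int(epoch_length * fs)
    epochs = []
    for e in range(n_epochs):
        t = (np.arange(n) + e * n) / fs
        ep = np.stack([a * np.sin(2 * np.pi * f * t + ph)
                       for f, ph, a in zip(freqs_per_channel, phases, amplitudes)])
        epochs.append(ep)
    return EpochSet(epochs, epoch_length, fs, band=band,
                    channel_labels=[f"CH{k:02d}" for k in range(n_ch)])
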