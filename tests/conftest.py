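import numpy as np
import pytest

from alphanet import synth
from alphanet.preprocess import Epochs


@pytest.fixture(scope="session")
def montage64():
    return synth.make_montage_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sine_epochs(freq, fs, epoch_s, n_epochs, n_channels=1, amplitude=1.0,
                phase=0.0, labels=None):
    """Epochs of a pure sinusoid, identical across channels and epochs."""
    n = int(epoch_s * fs)
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t + phase)
    blocks = np.tile(x, (n_epochs, n_channels, 1))
    labels = labels or [f"ch{i}" for i in range(n_channels)]
    return Epochs(blocks=blocks, fs=fs, channel_labels=labels)


@pytest.fixture()
def pair_design():
    """Tiny two-channel design with a strong pi/4-lag coupling, no noise."""
    mont = synth.make_simple_montage(["P3", "P5"])
    return synth.GroupDesign(
        montage=mont, n_per_group=2, fs=250.0, duration=60.0,
        noise_amplitude=0.0, nonscalp_noise_amplitude=0.0,
        couplings=[synth.CouplingSpec(("P3", "P5"), np.pi / 4, 1.0)], seed=11)
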