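import dendropy
import numpy as np
import pytest

from phylosong.features import Spectrogram


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def cherry_plus_outgroup():
    """((A:1,B:1):1,C:2); — hand-checkable cophenetic and VCV values."""
    return make_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def star5():
    """Five-tip star tree, equal unit branches: K = 1 exactly."""
    return make_tree("(A:1,B:1,C:1,D:1,E:1);")


def make_spectrogram(mags, sr=22050, fft=512, hop=256) -> Spectrogram:
    """Wrap a hand-built (bins x frames) magnitude array as a Spectrogram."""
    mags = np.asarray(mags, dtype=float)
    n_bins = mags.shape[0]
    bin_freqs = np.linspace(0, sr / 2, n_bins)
    frame_times = hop * np.arange(mags.shape[1]) / sr
    return Spectrogram(mags, bin_freqs, frame_times, fft=fft, hop=hop)


@pytest.fixture
def tone_waveform():
    from phylosong.features import Waveform

    sr = 22050
    t = np.arange(sr) / sr
    return Waveform(np.sin(2 * np.pi * 1000.0 * t), sr)
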