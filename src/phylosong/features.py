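"""Acoustic preprocessing and the nine spectral/temporal features.

Every recording is resampled to 22 050 Hz, band-pass filtered between
100 Hz and 10 kHz (4th-order Butterworth, applied forward-backward for zero
phase) and standardized to mean 0 / sd 1, so that all features are invariant
to the recording's absolute amplitude. Features are computed on a magnitude
short-time Fourier transform (fft 512, hop 256, Hann window, center-padded
frames):

================  =========================================================
rms_cv            coefficient of variation (sd/mean) of per-frame RMS
flux_logsd        ln(sd) of per-frame spectral flux (frame-to-frame squared
                  spectrum change)
entropy           Shannon entropy (bits) of the whole-vocalization mean
                  power spectrum
flatness_logmean  ln(mean over frames) of spectral flatness
                  (geometric/arithmetic mean of the power spectrum)
centroid_logmedian ln(median over frames) of the spectral centroid (Hz)
contrast1..4      ln(mean over frames) of peak/valley log-ratio within
                  0-500, 500-1000, 1000-2000 and 2000-4000 Hz
================  =========================================================

Per-recording vectors are averaged within species to give the species-level
feature table the distance matrices are built from.

Flatness orientation: the geometric/arithmetic-mean ratio is 1 for a flat
(noise-like) spectrum and tends to 0 for a pure tone. A companion
``tonality_index = 1 - flatness_index`` follows the opposite verbal
convention (0 = white noise, 1 = purely harmonic); the pipeline feature is
``ln(flatness_index)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
from scipy.io import wavfile

from .exceptions import DegenerateSignalError

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "rms_cv",
    "flux_logsd",
    "entropy",
    "flatness_logmean",
    "centroid_logmedian",
    "contrast1",
    "contrast2",
    "contrast3",
    "contrast4",
)

#: frequency bands (Hz) for the four spectral-contrast features
CONTRAST_BANDS = {1: (0.0, 500.0), 2: (500.0, 1000.0), 3: (1000.0, 2000.0), 4: (2000.0, 4000.0)}

POWER_FLOOR = 1e-10   # floor inside flatness/contrast power ratios
FLUX_EPS = 1e-12      # floor inside the flux log

DEFAULT_SR = 22050
DEFAULT_FFT = 512
DEFAULT_HOP = 256


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal: float samples plus sample rate (samples/s)."""

    samples: np.ndarray = field(repr=False)
    sample_rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude STFT: (frequency-bin x time-frame) nonnegative matrix."""

    magnitudes: np.ndarray = field(repr=False)
    bin_freqs: np.ndarray = field(repr=False)
    frame_times: np.ndarray = field(repr=False)
    fft: int
    hop: int
    window: str = "hann"

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]


# ---------------------------------------------------------------------------
# I/O and preprocessing
# ---------------------------------------------------------------------------

def read_wav(path) -> Waveform:
    """Read a RIFF WAV file (PCM 16/24/32 or float), downmixing to mono."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Waveform(data, sr)


def write_wav(path, w: Waveform) -> None:
    """Write a mono 16-bit PCM WAV file; samples are peak-limited to |x| <= 1."""
    x = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, int(round(w.sample_rate)), (x * 32767.0).astype(np.int16))


def preprocess(
    raw: Waveform,
    low_hz: float = 100.0,
    high_hz: float = 10000.0,
    target_sr: float = DEFAULT_SR,
) -> Waveform:
    """Resample, band-pass (low_hz-high_hz) and standardize to mean 0 / sd 1.

    Standardization is applied last so the unit-variance contract holds on
    the filtered signal. Raises :class:`DegenerateSignalError` if the signal
    has zero variance after filtering.
    """
    if len(raw.samples) == 0:
        raise DegenerateSignalError("empty waveform")
    if not 0 < low_hz < high_hz < target_sr / 2:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) must satisfy "
            f"0 < low < high < Nyquist ({target_sr / 2})"
        )
    x = raw.samples
    if abs(raw.sample_rate - target_sr) > 1e-9:
        frac = Fraction(target_sr / raw.sample_rate).limit_denominator(1000)
        x = scipy.signal.resample_poly(x, frac.numerator, frac.denominator)
    sos = scipy.signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=target_sr, output="sos"
    )
    x = scipy.signal.sosfiltfilt(sos, x)
    sd = x.std()
    if sd <= 1e-12:
        raise DegenerateSignalError("signal has zero variance after filtering")
    x = (x - x.mean()) / sd
    return Waveform(x, target_sr)


# ---------------------------------------------------------------------------
# spectrogram
# ---------------------------------------------------------------------------

def compute_spectrogram(
    w: Waveform, fft: int = DEFAULT_FFT, hop: int = DEFAULT_HOP
) -> Spectrogram:
    """Magnitude STFT with Hann window and center padding.

    The signal is zero-padded by fft//2 on each side and framed every ``hop``
    samples, giving ``1 + len//hop`` frames; frame t is centred on sample
    t*hop of the original signal. (The floor convention keeps the final
    frame at least half-filled with signal; a ceil convention would append a
    nearly empty frame that distorts envelope statistics.)
    """
    x = w.samples
    if len(x) < fft:
        raise DegenerateSignalError(
            f"signal too short ({len(x)} samples) for one {fft}-sample frame"
        )
    n_frames = 1 + len(x) // hop
    pad_left = fft // 2
    needed = (n_frames - 1) * hop + fft
    pad_right = max(0, needed - (len(x) + pad_left))
    xp = np.pad(x, (pad_left, pad_right))
    idx = np.arange(fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx]
    window = scipy.signal.get_window("hann", fft, fftbins=True)
    S = np.abs(np.fft.rfft(frames * window, axis=1)).T  # (bins, frames)
    bin_freqs = np.fft.rfftfreq(fft, d=1.0 / w.sample_rate)
    frame_times = hop * np.arange(n_frames) / w.sample_rate
    return Spectrogram(S, bin_freqs, frame_times, fft=fft, hop=hop)


# ---------------------------------------------------------------------------
# the nine features
# ---------------------------------------------------------------------------

def rms_cv(s: Spectrogram) -> float:
    """Coefficient of variation of per-frame RMS amplitude (unit-free)."""
    if s.n_frames < 2:
        raise ValueError("need at least two frames for an RMS envelope")
    r = np.sqrt(np.mean(s.magnitudes**2, axis=0))
    mean = r.mean()
    if mean <= 0:
        raise DegenerateSignalError("zero mean RMS amplitude")
    return float(r.std() / mean)


def flux_logsd(s: Spectrogram) -> float:
    """ln(sd) of per-frame spectral flux (squared spectrum difference)."""
    if s.n_frames < 3:
        raise ValueError("need at least three frames for spectral flux")
    F = np.sum(np.diff(s.magnitudes, axis=1) ** 2, axis=0)
    return float(np.log(F.std() + FLUX_EPS))


def spectral_entropy(s: Spectrogram) -> float:
    """Shannon entropy (bits) of the whole-vocalization mean power spectrum."""
    P = np.mean(s.magnitudes**2, axis=1)
    total = P.sum()
    if total <= 0:
        raise DegenerateSignalError("spectrogram carries zero power")
    p = P / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def _frame_flatness(s: Spectrogram) -> np.ndarray:
    power = np.maximum(s.magnitudes**2, POWER_FLOOR)
    gm = np.exp(np.mean(np.log(power), axis=0))
    am = np.mean(power, axis=0)
    return gm / am


def flatness_index(s: Spectrogram) -> float:
    """Mean over frames of spectral flatness: 1 = flat/noise-like, -> 0 = tonal."""
    return float(np.mean(_frame_flatness(s)))


def tonality_index(s: Spectrogram) -> float:
    """1 - flatness_index: 0 for white noise, -> 1 for a purely harmonic sound."""
    return 1.0 - flatness_index(s)


def flatness_logmean(s: Spectrogram) -> float:
    """ln of the time-averaged spectral flatness (the pipeline feature)."""
    return float(np.log(flatness_index(s)))


def centroid_logmedian(s: Spectrogram) -> float:
    """ln of the median over frames of the spectral centroid (Hz).

    Frames with zero total magnitude are dropped, not imputed.
    """
    totals = s.magnitudes.sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise DegenerateSignalError("all frames have zero magnitude")
    c = (s.bin_freqs @ s.magnitudes[:, keep]) / totals[keep]
    return float(np.log(np.median(c)))


def band_contrast(s: Spectrogram, band: int, alpha: float = 0.02) -> float:
    """Spectral contrast within one of the four frequency bands.

    Per frame, within the band's bins, peak = mean of the top alpha-fraction
    of magnitudes and valley = mean of the bottom alpha-fraction (at least
    one bin each); the per-frame contrast is log10((peak+eps)/(valley+eps)).
    The feature is ln(mean over frames of the per-frame contrast + eps).
    """
    if band not in CONTRAST_BANDS:
        raise ValueError(f"band must be one of {sorted(CONTRAST_BANDS)}")
    lo, hi = CONTRAST_BANDS[band]
    nyquist = s.bin_freqs[-1]
    if lo >= nyquist:
        raise ValueError(f"band {band} ({lo}-{hi} Hz) lies outside Nyquist")
    mask = (s.bin_freqs >= lo) & (s.bin_freqs < hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} contains fewer than two frequency bins")
    sub = np.sort(s.magnitudes[mask, :], axis=0)
    k = max(1, int(round(alpha * mask.sum())))
    valley = sub[:k, :].mean(axis=0)
    peak = sub[-k:, :].mean(axis=0)
    per_frame = np.log10((peak + POWER_FLOOR) / (valley + POWER_FLOOR))
    return float(np.log(per_frame.mean() + POWER_FLOOR))


# ---------------------------------------------------------------------------
# feature vectors and species aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    rms_cv: float
    flux_logsd: float
    entropy: float
    flatness_logmean: float
    centroid_logmedian: float
    contrast1: float
    contrast2: float
    contrast3: float
    contrast4: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_feature_vector(
    w: Waveform,
    fft: int = DEFAULT_FFT,
    hop: int = DEFAULT_HOP,
    recording_id: str | None = None,
) -> FeatureVector:
    """Compute the nine features of a (preprocessed) waveform."""
    try:
        s = compute_spectrogram(w, fft=fft, hop=hop)
        return FeatureVector(
            rms_cv=rms_cv(s),
            flux_logsd=flux_logsd(s),
            entropy=spectral_entropy(s),
            flatness_logmean=flatness_logmean(s),
            centroid_logmedian=centroid_logmedian(s),
            contrast1=band_contrast(s, 1),
            contrast2=band_contrast(s, 2),
            contrast3=band_contrast(s, 3),
            contrast4=band_contrast(s, 4),
        )
    except DegenerateSignalError as err:
        if recording_id is not None:
            raise DegenerateSignalError(f"{recording_id}: {err}") from err
        raise


@dataclass(frozen=True)
class SpeciesFeatureTable:
    """Species-mean feature values plus per-species recording counts.

    ``data`` is a DataFrame indexed by species ID with the nine feature
    columns; ``n_recordings`` gives the number of recordings averaged.
    """

    data: pd.DataFrame = field(repr=False)
    n_recordings: pd.Series = field(repr=False)

    @property
    def species(self) -> tuple:
        return tuple(self.data.index)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["n_recordings"] = self.n_recordings
        out.to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path) -> "SpeciesFeatureTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        n = df.pop("n_recordings").astype(int)
        return cls(df[list(FEATURE_NAMES)], n)


def aggregate_species_means(per_recording) -> SpeciesFeatureTable:
    """Average per-recording feature vectors within species.

    ``per_recording`` maps species ID to a sequence of FeatureVector (or
    9-vectors). A species with a single recording triggers a warning: species
    means from one exemplar carry no within-species averaging.
    """
    rows, counts = {}, {}
    for species, vecs in per_recording.items():
        vecs = list(vecs)
        if not vecs:
            raise ValueError(f"species {species!r} has no recordings")
        arrs = [
            v.to_array() if isinstance(v, FeatureVector) else np.asarray(v, float)
            for v in vecs
        ]
        if any(a.shape != (9,) for a in arrs):
            raise ValueError(f"species {species!r}: feature vectors must have length 9")
        if len(arrs) == 1:
            warnings.warn(
                f"species {species!r} has a single recording; its species mean "
                "is that one vector",
                stacklevel=2,
            )
        rows[str(species)] = np.mean(arrs, axis=0)
        counts[str(species)] = len(arrs)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    data = data.sort_index()
    n = pd.Series(counts).sort_index()
    return SpeciesFeatureTable(data, n)
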