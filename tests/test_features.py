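"""Preprocessing, spectrogram and the nine acoustic features."""

import numpy as np
import pytest

from phylosong.exceptions import DegenerateSignalError
from phylosong.features import (
    FEATURE_NAMES,
    Waveform,
    aggregate_species_means,
    band_contrast,
    centroid_logmedian,
    compute_spectrogram,
    extract_feature_vector,
    flatness_index,
    flux_logsd,
    preprocess,
    read_wav,
    rms_cv,
    spectral_entropy,
    tonality_index,
    write_wav,
)
from .conftest import make_spectrogram

SR = 22050


def tone(freq, duration=1.0, sr=SR, amp=1.0):
    t = np.arange(int(duration * sr)) / sr
    return Waveform(amp * np.sin(2 * np.pi * freq * t), sr)


class TestPreprocess:
    def test_standardizes_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        w = preprocess(Waveform(rng.standard_normal(SR) + 3.0, SR))
        assert abs(w.samples.mean()) < 1e-6
        assert abs(w.samples.std() - 1.0) < 1e-6

    def test_band_pass_rejects_50hz_by_20db(self):
        low = preprocess(tone(50.0, amp=1.0))
        mid = preprocess(tone(1000.0, amp=1.0))
        # standardization hides absolute gain; compare pre-standardization
        # by re-running the filter stage alone via relative spectral content
        import scipy.signal

        sos = scipy.signal.butter(4, [100, 10000], btype="bandpass", fs=SR,
                                  output="sos")
        r50 = np.sqrt(np.mean(scipy.signal.sosfiltfilt(sos, tone(50.0).samples) ** 2))
        r1k = np.sqrt(np.mean(scipy.signal.sosfiltfilt(sos, tone(1000.0).samples) ** 2))
        assert 20 * np.log10(r1k / r50) >= 20.0
        assert len(low.samples) == len(mid.samples)

    def test_native_rate_input_keeps_length(self):
        w = preprocess(tone(500.0))
        assert len(w.samples) == SR

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateSignalError):
            preprocess(Waveform(np.ones(SR), SR))

    def test_resamples_to_target_rate(self):
        t = np.arange(44100) / 44100
        w = preprocess(Waveform(np.sin(2 * np.pi * 440 * t), 44100))
        assert w.sample_rate == SR
        assert abs(len(w.samples) - SR) <= 2


class TestSpectrogram:
    def test_tone_peaks_at_nearest_bin(self, tone_waveform):
        s = compute_spectrogram(tone_waveform)
        peak_bins = s.magnitudes[:, 2:-2].argmax(axis=0)
        expected = np.argmin(np.abs(s.bin_freqs - 1000.0))
        assert np.all(peak_bins == expected)

    def test_frame_count(self):
        for n in (512, 1024, 4096, 22016):  # multiples of the hop
            w = Waveform(np.random.default_rng(1).standard_normal(n), SR)
            s = compute_spectrogram(w)
            assert s.n_frames == 1 + n // 256

    def test_parseval_energy_within_5pct(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(SR)
        s = compute_spectrogram(Waveform(x, SR))
        # rfft: double the energy of non-DC/non-Nyquist bins
        spec_e = (s.magnitudes**2).sum() + (s.magnitudes[1:-1] ** 2).sum()
        import scipy.signal

        win = scipy.signal.get_window("hann", 512, fftbins=True)
        xp = np.pad(x, (256, 512))
        frame_e = sum(
            ((xp[i * 256:i * 256 + 512] * win) ** 2).sum()
            for i in range(s.n_frames)
        )
        assert abs(spec_e / 512 - frame_e) / frame_e < 0.05

    def test_too_short_raises(self):
        with pytest.raises(DegenerateSignalError):
            compute_spectrogram(Waveform(np.ones(100), SR))


class TestRmsCV:
    def test_steady_tone_near_zero(self, tone_waveform):
        assert rms_cv(compute_spectrogram(tone_waveform)) < 0.05

    def test_gated_tone_near_one(self):
        # 50% duty cycle, gate period 0.5 s >> frame: envelope is two-point
        # {r, 0}, for which sd equals the mean
        t = np.arange(2 * SR) / SR
        gate = ((t % 0.5) < 0.25).astype(float)
        w = Waveform(np.sin(2 * np.pi * 2000 * t) * gate, SR)
        assert abs(rms_cv(compute_spectrogram(w)) - 1.0) < 0.1

    def test_amplitude_scale_invariant(self, tone_waveform):
        s1 = compute_spectrogram(tone_waveform)
        s2 = compute_spectrogram(
            Waveform(10.0 * tone_waveform.samples, SR)
        )
        assert rms_cv(s1) == pytest.approx(rms_cv(s2), rel=1e-12)


class TestFlux:
    def test_identical_frames_floor(self):
        s = make_spectrogram(np.tile([[1.0], [2.0], [3.0]], (1, 5)))
        assert flux_logsd(s) == pytest.approx(np.log(1e-12))

    def test_alternating_exceeds_steady(self):
        steady = make_spectrogram(np.tile([[1.0], [0.0], [1.0]], (1, 8)))
        # two-tone square sequence AABB AABB: flux alternates between zero
        # (hold) and a jump, so its sd is positive
        frames = np.zeros((3, 8))
        frames[0, [0, 1, 4, 5]] = 1.0
        frames[2, [2, 3, 6, 7]] = 1.0
        alternating = make_spectrogram(frames)
        assert flux_logsd(alternating) > flux_logsd(steady)


class TestEntropy:
    def test_point_mass_zero_bits(self):
        m = np.zeros((257, 4))
        m[40] = 1.0
        assert spectral_entropy(make_spectrogram(m)) == pytest.approx(0.0)

    def test_uniform_257_bins(self):
        m = np.ones((257, 4))
        assert spectral_entropy(make_spectrogram(m)) == pytest.approx(
            np.log2(257)
        )

    def test_two_equal_bins_one_bit(self):
        m = np.zeros((257, 4))
        m[[10, 20]] = 1.0
        assert spectral_entropy(make_spectrogram(m)) == pytest.approx(1.0)


class TestFlatness:
    def test_impulse_frame_is_flat(self):
        # unit impulse, rectangular window: exactly flat magnitude spectrum
        mags = np.abs(np.fft.rfft(np.eye(512)[0]))[:, None]
        s = make_spectrogram(mags)
        assert flatness_index(s) == pytest.approx(1.0, abs=0.01)
        assert tonality_index(s) == pytest.approx(0.0, abs=0.01)

    def test_sine_frame_is_tonal(self):
        # integer cycles per frame: energy in one bin pair
        x = np.sin(2 * np.pi * 32 * np.arange(512) / 512)
        mags = np.abs(np.fft.rfft(x))[:, None]
        s = make_spectrogram(mags)
        assert flatness_index(s) == pytest.approx(0.0, abs=0.05)
        assert tonality_index(s) == pytest.approx(1.0, abs=0.05)

    def test_amplitude_scale_invariant(self):
        rng = np.random.default_rng(3)
        m = rng.random((257, 6)) + 0.1
        a = flatness_index(make_spectrogram(m))
        b = flatness_index(make_spectrogram(100 * m))
        assert a == pytest.approx(b, rel=1e-9)


class TestCentroid:
    def test_pure_1khz(self, tone_waveform):
        c = centroid_logmedian(compute_spectrogram(tone_waveform))
        assert abs(np.exp(c) - 1000.0) < SR / 512  # within one bin

    def test_two_tone_symmetry(self):
        t = np.arange(SR) / SR
        w = Waveform(
            np.sin(2 * np.pi * 500 * t) + np.sin(2 * np.pi * 1500 * t), SR
        )
        c = centroid_logmedian(compute_spectrogram(w))
        assert abs(np.exp(c) - 1000.0) < 1.5 * SR / 512

    def test_flat_spectrum_mean_bin_freq(self):
        n_bins = 257
        m = np.ones((n_bins, 4))
        s = make_spectrogram(m)
        c = centroid_logmedian(s)
        assert np.exp(c) == pytest.approx(s.bin_freqs.mean())  # ~5512.5 Hz


class TestBandContrast:
    def test_flat_band_zero_contrast(self):
        m = np.ones((257, 4))
        s = make_spectrogram(m)
        # feature = ln(mean contrast + eps) with contrast 0 per frame
        assert band_contrast(s, 2) == pytest.approx(np.log(1e-10))

    def test_tenfold_ratio(self):
        s0 = make_spectrogram(np.ones((257, 4)))
        band2 = (s0.bin_freqs >= 500) & (s0.bin_freqs < 1000)
        m = np.ones((257, 4))
        idx = np.where(band2)[0]
        m[idx[-1]] = 10.0  # top bin 10x the rest
        m[idx[0]] = 1.0
        s = make_spectrogram(m)
        # alpha=0.02 of 12 bins -> 1 bin each: contrast log10(10/1) = 1
        assert band_contrast(s, 2) == pytest.approx(np.log(1.0), abs=1e-6)

    def test_band_specific_peaks(self):
        base = np.ones((257, 4))
        s0 = make_spectrogram(base)
        m = base.copy()
        band3 = (s0.bin_freqs >= 1000) & (s0.bin_freqs < 2000)
        m[np.where(band3)[0][5]] = 20.0
        s = make_spectrogram(m)
        assert band_contrast(s, 3) > band_contrast(s0, 3) + 1.0
        for b in (1, 2, 4):
            assert band_contrast(s, b) == pytest.approx(
                band_contrast(s0, b), abs=1e-9
            )

    def test_bad_band_raises(self):
        s = make_spectrogram(np.ones((257, 4)))
        with pytest.raises(ValueError):
            band_contrast(s, 9)


class TestHandComputedOracle:
    """rms_cv, entropy and centroid on a tiny 3x4 spectrogram, vs direct
    arithmetic carried out independently of the implementation."""

    def test_three_by_four(self):
        m = np.array(
            [[1.0, 2.0, 1.0, 0.5],
             [0.5, 1.0, 2.0, 1.0],
             [2.0, 0.5, 1.0, 2.0]]
        )
        s = make_spectrogram(m)
        r = np.sqrt((m**2).mean(axis=0))
        assert rms_cv(s) == pytest.approx(r.std() / r.mean(), abs=1e-9)
        P = (m**2).mean(axis=1)
        p = P / P.sum()
        assert spectral_entropy(s) == pytest.approx(
            -(p * np.log2(p)).sum(), abs=1e-9
        )
        c = (s.bin_freqs @ m) / m.sum(axis=0)
        assert centroid_logmedian(s) == pytest.approx(
            np.log(np.median(c)), abs=1e-9
        )


class TestFeatureVector:
    def test_deterministic(self, tone_waveform):
        w = preprocess(tone_waveform)
        v1 = extract_feature_vector(w).to_array()
        v2 = extract_feature_vector(w).to_array()
        assert np.array_equal(v1, v2)
        assert v1.shape == (9,)
        assert np.all(np.isfinite(v1))

    def test_tone_vs_noise_ordering(self):
        rng = np.random.default_rng(4)
        w_tone = preprocess(tone(2000.0))
        w_noise = preprocess(Waveform(rng.standard_normal(SR), SR))
        ft = extract_feature_vector(w_tone)
        fn = extract_feature_vector(w_noise)
        assert ft.flatness_logmean < fn.flatness_logmean
        assert ft.entropy < fn.entropy

    def test_amplitude_invariance_after_preprocess(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(SR)
        for scale in (0.1, 10.0):
            a = extract_feature_vector(preprocess(Waveform(x, SR))).to_array()
            b = extract_feature_vector(
                preprocess(Waveform(scale * x, SR))
            ).to_array()
            np.testing.assert_allclose(a, b, rtol=1e-7, atol=1e-9)


class TestAggregation:
    def test_single_recording_is_identity_with_warning(self):
        v = np.arange(9.0)
        with pytest.warns(UserWarning, match="single recording"):
            t = aggregate_species_means({"spA": [v]})
        np.testing.assert_array_equal(t.data.loc["spA"].to_numpy(), v)
        assert t.n_recordings["spA"] == 1

    def test_mean_of_two(self):
        t = aggregate_species_means({"spA": [np.full(9, 1.0), np.full(9, 3.0)]})
        assert np.all(t.data.loc["spA"] == 2.0)

    def test_order_invariant(self):
        a, b, c = (np.full(9, v) for v in (1.0, 2.0, 6.0))
        t1 = aggregate_species_means({"s": [a, b, c]})
        t2 = aggregate_species_means({"s": [c, a, b]})
        assert t1.data.equals(t2.data)

    def test_empty_species_raises(self):
        with pytest.raises(ValueError):
            aggregate_species_means({"spA": []})

    def test_csv_round_trip(self, tmp_path):
        t = aggregate_species_means(
            {"a": [np.arange(9.0), np.arange(9.0) + 1], "b": [np.ones(9)]}
        )
        path = tmp_path / "feat.csv"
        t.to_csv(path)
        from phylosong.features import SpeciesFeatureTable

        t2 = SpeciesFeatureTable.from_csv(path)
        np.testing.assert_allclose(t.data.to_numpy(), t2.data.to_numpy())
        assert list(t2.data.columns) == list(FEATURE_NAMES)


class TestWavIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        w = Waveform(np.clip(rng.standard_normal(1000) * 0.2, -1, 1), SR)
        path = tmp_path / "x.wav"
        write_wav(path, w)
        back = read_wav(path)
        assert back.sample_rate == SR
        np.testing.assert_allclose(back.samples, w.samples, atol=1e-4)
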