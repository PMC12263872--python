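import numpy as np
import pytest
import scipy.fft
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmspeech.audio_features import (
    AudioSignal,
    MfccConfig,
    dct_cepstra,
    extract_mfcc,
    frame_signal,
    functionals,
    hz_to_mel,
    load_wav,
    log_mel_energies,
    mel_filterbank,
    mel_to_hz,
    power_spectrum,
    preemphasize,
)
from swarmspeech.errors import ConfigurationError, InvalidInputError


def reference_mfcc(samples, sr, cfg):
    """Independent MFCC implementation from scipy primitives (test oracle)."""
    y = scipy.signal.lfilter([1.0, -cfg.preemph], [1.0], samples)
    frame_len = round(cfg.frame_length_ms * sr / 1000)
    hop = round(cfg.hop_length_ms * sr / 1000)
    n_frames = (len(y) - frame_len) // hop + 1
    window = scipy.signal.get_window("hamming", frame_len, fftbins=False)
    frames = np.stack([y[i * hop : i * hop + frame_len] * window for i in range(n_frames)])
    spec = np.abs(scipy.fft.rfft(frames, n=cfg.n_fft, axis=1)) ** 2 / cfg.n_fft
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    pts = np.floor(
        (cfg.n_fft + 1) * imel(np.linspace(mel(cfg.fmin), mel(cfg.fmax), cfg.n_mels + 2)) / sr
    ).astype(int)
    n_bins = cfg.n_fft // 2 + 1
    bank = np.zeros((cfg.n_mels, n_bins))
    for m in range(cfg.n_mels):
        left, centre, right = pts[m], pts[m + 1], pts[m + 2]
        for k in range(left, min(right + 1, n_bins)):
            if k < centre:
                bank[m, k] = (k - left) / (centre - left)
            elif k == centre:
                bank[m, k] = 1.0
            else:
                bank[m, k] = (right - k) / (right - centre)
    log_mel = np.log(np.maximum(spec @ bank.T, cfg.log_floor))
    return scipy.fft.dct(log_mel, type=2, norm="ortho", axis=1)[:, : cfg.n_coeffs]


class TestPreemphasize:
    def test_zero_coeff_is_identity(self, one_second_tone):
        out = preemphasize(one_second_tone, 0.0)
        np.testing.assert_array_equal(out.samples, one_second_tone.samples)

    def test_constant_signal(self):
        sig = AudioSignal(np.ones(10), 16000)
        out = preemphasize(sig, 0.97)
        assert out.samples[0] == 1.0
        np.testing.assert_allclose(out.samples[1:], 0.03)

    def test_hand_example(self):
        sig = AudioSignal(np.array([0.0, 1.0, 0.0]), 16000)
        out = preemphasize(sig, 0.5)
        np.testing.assert_allclose(out.samples, [0.0, 1.0, -0.5])

    def test_empty_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            AudioSignal(np.array([]), 16000)

    def test_bad_coeff_rejected(self, one_second_tone):
        with pytest.raises(InvalidInputError):
            preemphasize(one_second_tone, 1.0)


class TestFraming:
    def test_one_second_16k(self, one_second_tone, default_cfg):
        frames = frame_signal(one_second_tone, default_cfg)
        assert frames.shape == (98, 400)

    def test_exact_one_frame(self, default_cfg):
        sig = AudioSignal(np.ones(400), 16000)
        assert frame_signal(sig, default_cfg).shape[0] == 1

    def test_no_overlap(self):
        cfg = MfccConfig(frame_length_ms=25.0, hop_length_ms=25.0)
        sig = AudioSignal(np.ones(1200), 16000)
        assert frame_signal(sig, cfg).shape[0] == 3

    def test_too_short_rejected(self, default_cfg):
        with pytest.raises(InvalidInputError):
            frame_signal(AudioSignal(np.ones(399), 16000), default_cfg)

    def test_hamming_applied(self, default_cfg):
        sig = AudioSignal(np.ones(400), 16000)
        frames = frame_signal(sig, default_cfg)
        expected = scipy.signal.get_window("hamming", 400, fftbins=False)
        np.testing.assert_allclose(frames[0], expected, atol=1e-12)

    @given(
        length=st.integers(min_value=400, max_value=40000),
        hop=st.integers(min_value=40, max_value=400),
    )
    @settings(max_examples=50, deadline=None)
    def test_frame_count_formula(self, length, hop):
        cfg = MfccConfig(frame_length_ms=25.0, hop_length_ms=hop / 16.0)
        sig = AudioSignal(np.zeros(length), 16000)
        frames = frame_signal(sig, cfg)
        assert frames.shape[0] == (length - 400) // hop + 1


class TestPowerSpectrum:
    def test_zero_frame(self):
        out = power_spectrum(np.zeros((2, 64)), 64)
        np.testing.assert_array_equal(out, np.zeros((2, 33)))

    def test_sinusoid_peak_matches_brute_force_dft(self):
        n_fft = 64
        k0 = 7
        frame = np.sin(2 * np.pi * k0 * np.arange(n_fft) / n_fft)
        out = power_spectrum(frame, n_fft)[0]
        # brute-force DFT oracle
        brute = np.array(
            [
                abs(sum(frame[n] * np.exp(-2j * np.pi * k * n / n_fft) for n in range(n_fft))) ** 2
                for k in range(n_fft // 2 + 1)
            ]
        ) / n_fft
        np.testing.assert_allclose(out, brute, atol=1e-9)
        assert np.argmax(out) == k0

    def test_quadratic_scaling(self, rng):
        frame = rng.standard_normal(64)
        base = power_spectrum(frame, 64)
        np.testing.assert_allclose(power_spectrum(3.0 * frame, 64), 9.0 * base, rtol=1e-12)

    def test_non_power_of_two_warns(self):
        with pytest.warns(RuntimeWarning):
            power_spectrum(np.ones((1, 50)), 60)

    def test_nonnegative(self, rng):
        assert (power_spectrum(rng.standard_normal((5, 64)), 64) >= 0).all()


class TestMelFilterbank:
    def test_mel_formula_anchors(self):
        assert hz_to_mel(0.0) == 0.0
        assert np.isclose(hz_to_mel(700.0), 781.1728387480312)
        assert np.isclose(mel_to_hz(hz_to_mel(1234.5)), 1234.5)

    def test_rows_are_contiguous_triangles(self, default_cfg):
        bank = mel_filterbank(default_cfg, 16000)
        assert (bank >= 0).all()
        for row in bank:
            support = np.flatnonzero(row)
            assert support.size > 0
            assert np.array_equal(support, np.arange(support[0], support[-1] + 1))

    def test_peak_bin_exclusive_to_own_filter(self, default_cfg):
        bank = mel_filterbank(default_cfg, 16000)
        for m in range(1, default_cfg.n_mels - 1):
            peak = np.argmax(bank[m])
            assert bank[m, peak] == 1.0
            assert bank[m - 1, peak] == 0.0
            assert bank[m + 1, peak] == 0.0

    def test_too_many_filters_rejected(self):
        cfg = MfccConfig(n_fft=64, n_mels=60, n_coeffs=10)
        with pytest.raises(ConfigurationError):
            mel_filterbank(cfg, 16000)

    def test_fmax_above_nyquist_rejected(self, default_cfg):
        with pytest.raises(ConfigurationError):
            mel_filterbank(default_cfg, 8000)


class TestLogMel:
    def test_silent_frame_hits_floor(self, default_cfg):
        bank = mel_filterbank(default_cfg, 16000)
        out = log_mel_energies(np.zeros((3, 257)), bank, 1e-10)
        np.testing.assert_allclose(out, np.log(1e-10))

    def test_doubling_adds_log2(self, rng, default_cfg):
        bank = mel_filterbank(default_cfg, 16000)
        spec = rng.uniform(1.0, 2.0, size=(4, 257))
        base = log_mel_energies(spec, bank, 1e-10)
        np.testing.assert_allclose(log_mel_energies(2 * spec, bank, 1e-10), base + np.log(2.0))

    def test_single_bin_single_filter(self, default_cfg):
        bank = mel_filterbank(default_cfg, 16000)
        m, k = 5, int(np.argmax(bank[5]) - 1)
        w = bank[m, k]
        assert w > 0
        spec = np.zeros((1, 257))
        spec[0, k] = 1.0
        out = log_mel_energies(spec, bank, 1e-10)
        assert np.isclose(out[0, m], np.log(w))


class TestDct:
    def test_constant_row(self):
        n_mels = 40
        out = dct_cepstra(np.full((1, n_mels), 3.0), n_mels)
        assert np.isclose(out[0, 0], 3.0 * np.sqrt(n_mels))
        np.testing.assert_allclose(out[0, 1:], 0.0, atol=1e-12)

    def test_orthonormal_roundtrip(self, rng):
        x = rng.standard_normal((4, 20))
        full = dct_cepstra(x, 20)
        back = scipy.fft.idct(full, type=2, norm="ortho", axis=1)
        np.testing.assert_allclose(back, x, atol=1e-10)

    def test_too_many_coeffs_rejected(self):
        with pytest.raises(ConfigurationError):
            dct_cepstra(np.zeros((2, 10)), 11)


class TestExtractMfcc:
    def test_deterministic(self, one_second_tone, default_cfg):
        a = extract_mfcc(one_second_tone, default_cfg)
        b = extract_mfcc(one_second_tone, default_cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shape_contract(self, one_second_tone, default_cfg):
        seq = extract_mfcc(one_second_tone, default_cfg)
        assert seq.values.shape == (98, 13)
        assert seq.frame_times.shape == (98,)

    def test_matches_reference_oracle(self, rng, default_cfg):
        for _ in range(10):
            samples = 0.3 * rng.standard_normal(rng.integers(8000, 24000))
            sig = AudioSignal(samples, 16000)
            ours = extract_mfcc(sig, default_cfg).values
            ref = reference_mfcc(samples, 16000, default_cfg)
            np.testing.assert_allclose(ours, ref, atol=1e-4)

    @pytest.mark.parametrize("gain", [0.5, 2.0, 10.0])
    def test_scale_invariance_above_coeff0(self, noise_signal, default_cfg, gain):
        base = extract_mfcc(noise_signal, default_cfg).values
        scaled_sig = AudioSignal(gain * noise_signal.samples, 16000)
        scaled = extract_mfcc(scaled_sig, default_cfg).values
        np.testing.assert_allclose(scaled[:, 1:], base[:, 1:], atol=1e-6)
        # coefficient 0 shifts by sqrt(n_mels) * log(gain^2)
        np.testing.assert_allclose(
            scaled[:, 0] - base[:, 0],
            np.sqrt(default_cfg.n_mels) * np.log(gain**2),
            atol=1e-6,
        )

    @pytest.mark.parametrize(
        "samples",
        [
            np.zeros(16000),
            np.concatenate([np.zeros(8000), [1.0], np.zeros(7999)]),
            np.tile([1.0, -1.0], 8000),
        ],
        ids=["silence", "impulse", "square"],
    )
    def test_adversarial_inputs_finite(self, samples, default_cfg):
        seq = extract_mfcc(AudioSignal(samples, 16000), default_cfg)
        assert np.isfinite(seq.values).all()


class TestFunctionals:
    def test_constant_sequence(self, default_cfg, one_second_tone):
        seq = extract_mfcc(one_second_tone, default_cfg)
        const = type(seq)(
            values=np.tile(seq.values[0], (5, 1)),
            frame_times=seq.frame_times[:5],
            sample_rate=16000,
            config=default_cfg,
        )
        vec = functionals(const)
        stats = vec.values.reshape(13, 4)
        np.testing.assert_allclose(stats[:, 1], 0.0, atol=1e-12)  # sd
        np.testing.assert_allclose(stats[:, 0], stats[:, 2])  # mean == min
        np.testing.assert_allclose(stats[:, 0], stats[:, 3])  # mean == max

    def test_dimension_and_names(self, one_second_tone, default_cfg):
        vec = functionals(extract_mfcc(one_second_tone, default_cfg))
        assert vec.values.size == 52
        assert vec.feature_names[:4] == ("c00_mean", "c00_sd", "c00_min", "c00_max")
        assert "c03_sd" in vec.feature_names
        assert len(set(vec.feature_names)) == 52

    def test_frame_order_invariance(self, one_second_tone, default_cfg, rng):
        seq = extract_mfcc(one_second_tone, default_cfg)
        perm = rng.permutation(seq.n_frames)
        shuffled = type(seq)(
            values=seq.values[perm],
            frame_times=seq.frame_times,
            sample_rate=16000,
            config=default_cfg,
        )
        np.testing.assert_allclose(functionals(shuffled).values, functionals(seq).values)

    def test_single_frame_rejected(self, one_second_tone, default_cfg):
        seq = extract_mfcc(one_second_tone, default_cfg)
        short = type(seq)(
            values=seq.values[:1],
            frame_times=seq.frame_times[:1],
            sample_rate=16000,
            config=default_cfg,
        )
        with pytest.raises(InvalidInputError):
            functionals(short)


class TestSequenceCsv:
    def test_roundtrip(self, tmp_path, one_second_tone, default_cfg):
        from swarmspeech.audio_features import load_sequence_csv, save_sequence_csv

        seq = extract_mfcc(one_second_tone, default_cfg)
        path = tmp_path / "seq.csv"
        save_sequence_csv(seq, path)
        assert path.read_text().splitlines()[0].startswith("c00,c01")
        values, times = load_sequence_csv(path)
        np.testing.assert_allclose(values, seq.values, atol=1e-10)
        np.testing.assert_allclose(times, seq.frame_times, atol=1e-10)


class TestWavIo:
    def test_pcm16_roundtrip(self, tmp_path, one_second_tone):
        import scipy.io.wavfile

        path = tmp_path / "tone.wav"
        scipy.io.wavfile.write(
            path, 16000, (one_second_tone.samples * 32767).astype(np.int16)
        )
        sig = load_wav(path)
        assert sig.sample_rate == 16000
        assert np.max(np.abs(sig.samples)) <= 1.0
        np.testing.assert_allclose(sig.samples, one_second_tone.samples, atol=1e-4)

    def test_stereo_warns_and_averages(self, tmp_path, rng):
        import scipy.io.wavfile

        path = tmp_path / "stereo.wav"
        data = (rng.uniform(-0.5, 0.5, size=(1000, 2)) * 32767).astype(np.int16)
        scipy.io.wavfile.write(path, 16000, data)
        with pytest.warns(RuntimeWarning):
            sig = load_wav(path)
        assert sig.samples.shape == (1000,)
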