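"""MFCC extraction from first principles.

The chain is the classic one: pre-emphasis -> overlapping Hamming-windowed
frames -> magnitude-squared FFT -> triangular Mel filterbank (HTK Mel scale,
``2595 * log10(1 + f/700)``) -> log with an absolute floor -> orthonormal
type-II DCT, keeping the first ``n_coeffs`` coefficients.  Coefficient 0 (a
log-energy proxy) is retained; downstream feature selection may drop it.

Frames are taken without edge padding, so the frame count is exactly
``floor((len - frame_len) / hop) + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.io.wavfile

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "AudioSignal",
    "MfccConfig",
    "FeatureSequence",
    "FeatureVector",
    "load_wav",
    "preemphasize",
    "frame_signal",
    "power_spectrum",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "log_mel_energies",
    "dct_cepstra",
    "extract_mfcc",
    "functionals",
]

FUNCTIONAL_NAMES = ("mean", "sd", "min", "max")


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio signal with its sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidInputError("samples must be a non-empty 1-D array")
        if not np.isfinite(samples).all():
            raise InvalidInputError("samples must be finite")
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class MfccConfig:
    """Parameters of the MFCC chain.  Defaults are standard 16 kHz speech settings."""

    frame_length_ms: float = 25.0
    hop_length_ms: float = 10.0
    n_fft: int = 512
    n_mels: int = 40
    n_coeffs: int = 13
    preemph: float = 0.97
    fmin: float = 0.0
    fmax: float = 8000.0
    log_floor: float = 1e-10

    def __post_init__(self):
        if self.hop_length_ms > self.frame_length_ms:
            raise ConfigurationError("hop_length_ms must not exceed frame_length_ms")
        if not (0.0 <= self.preemph < 1.0):
            raise ConfigurationError("preemph must be in [0, 1)")
        if self.n_coeffs > self.n_mels:
            raise ConfigurationError("n_coeffs must not exceed n_mels")
        if self.fmin >= self.fmax:
            raise ConfigurationError("fmin must be below fmax")
        if self.log_floor <= 0:
            raise ConfigurationError("log_floor must be positive")
        if min(self.frame_length_ms, self.hop_length_ms) <= 0:
            raise ConfigurationError("frame and hop lengths must be positive")
        if min(self.n_fft, self.n_mels, self.n_coeffs) < 1:
            raise ConfigurationError("n_fft, n_mels and n_coeffs must be positive")

    def frame_length(self, sample_rate: int) -> int:
        return int(round(self.frame_length_ms * sample_rate / 1000.0))

    def hop_length(self, sample_rate: int) -> int:
        return int(round(self.hop_length_ms * sample_rate / 1000.0))


@dataclass(frozen=True)
class FeatureSequence:
    """Per-recording MFCC matrix (frames x coefficients) with frame timing."""

    values: np.ndarray  # (T, n_coeffs)
    frame_times: np.ndarray  # (T,) seconds, frame start times
    sample_rate: int
    config: MfccConfig

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_coeffs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureVector:
    """Recording-level functional summary of a FeatureSequence."""

    values: np.ndarray  # (d,)
    feature_names: tuple

    def __post_init__(self):
        if len(self.feature_names) != len(set(self.feature_names)):
            raise InvalidInputError("feature names must be unique")
        if len(self.feature_names) != np.asarray(self.values).size:
            raise InvalidInputError("values and feature_names length mismatch")


def load_wav(path) -> AudioSignal:
    """Read a WAV file (PCM or float) as a normalized mono AudioSignal.

    Integer PCM is scaled by the type's full scale; stereo input is averaged
    to mono with a warning.  After loading, ``max |sample| <= 1``.
    """
    sample_rate, data = scipy.io.wavfile.read(path)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input averaged to mono", RuntimeWarning)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        samples = samples / peak
    return AudioSignal(samples=samples, sample_rate=int(sample_rate))


def preemphasize(signal: AudioSignal, coeff: float) -> AudioSignal:
    """First-order high-pass difference: y[t] = x[t] - coeff * x[t-1], y[0] = x[0]."""
    if not (0.0 <= coeff < 1.0):
        raise InvalidInputError("pre-emphasis coefficient must be in [0, 1)")
    x = signal.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coeff * x[:-1]
    return replace(signal, samples=y)


def hamming_window(length: int) -> np.ndarray:
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1)) if length > 1 else np.ones(1)


def frame_signal(signal: AudioSignal, cfg: MfccConfig, window: str = "hamming") -> np.ndarray:
    """Slice the signal into overlapping windowed frames.

    Returns a (T, L) matrix with T = floor((len - L) / H) + 1; no edge
    padding or centering is applied.
    """
    frame_len = cfg.frame_length(signal.sample_rate)
    hop = cfg.hop_length(signal.sample_rate)
    n = len(signal)
    if n < frame_len:
        raise InvalidInputError(
            f"signal of {n} samples is shorter than one frame ({frame_len} samples)"
        )
    n_frames = (n - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = signal.samples[idx]
    if window == "hamming":
        frames = frames * hamming_window(frame_len)[None, :]
    elif window != "rectangular":
        raise ConfigurationError(f"unknown window {window!r}")
    return frames


def power_spectrum(frames: np.ndarray, n_fft: int) -> np.ndarray:
    """Periodogram of each frame: |rFFT|^2 / n_fft over n_fft points."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if n_fft < frames.shape[1]:
        raise InvalidInputError(
            f"n_fft={n_fft} smaller than frame length {frames.shape[1]}"
        )
    if n_fft & (n_fft - 1):
        warnings.warn(f"n_fft={n_fft} is not a power of two; FFT will be slower", RuntimeWarning)
    spectrum = np.fft.rfft(frames, n=n_fft, axis=1)
    return (spectrum.real**2 + spectrum.imag**2) / n_fft


def hz_to_mel(f):
    """HTK Mel scale: m = 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: MfccConfig, sample_rate: int) -> np.ndarray:
    """Triangular filters with unit peaks at n_mels points even on the Mel scale.

    Filter centres are snapped to FFT bins, so each interior filter's peak bin
    carries zero weight in both neighbouring filters.  Returns an
    (n_mels, n_fft // 2 + 1) matrix.
    """
    if cfg.fmax > sample_rate / 2.0:
        raise ConfigurationError(
            f"fmax={cfg.fmax} exceeds Nyquist frequency {sample_rate / 2.0}"
        )
    mel_pts = np.linspace(hz_to_mel(cfg.fmin), hz_to_mel(cfg.fmax), cfg.n_mels + 2)
    bin_pts = np.floor((cfg.n_fft + 1) * mel_to_hz(mel_pts) / sample_rate).astype(int)
    n_bins = cfg.n_fft // 2 + 1
    bank = np.zeros((cfg.n_mels, n_bins))
    for m in range(cfg.n_mels):
        left, centre, right = bin_pts[m], bin_pts[m + 1], bin_pts[m + 2]
        if left == centre or centre == right:
            raise ConfigurationError(
                f"empty Mel filter {m}: n_mels={cfg.n_mels} too large for "
                f"n_fft={cfg.n_fft} between {cfg.fmin} and {cfg.fmax} Hz"
            )
        up = np.arange(left, centre)
        bank[m, up] = (up - left) / (centre - left)
        down = np.arange(centre, right + 1)
        bank[m, down[down < n_bins]] = (
            (right - down[down < n_bins]) / (right - centre)
        )
        bank[m, centre] = 1.0
    return bank


def log_mel_energies(power_spec: np.ndarray, filterbank: np.ndarray, log_floor: float) -> np.ndarray:
    """log(max(filterbank . power, floor)); finite even for silent frames."""
    if power_spec.shape[1] != filterbank.shape[1]:
        raise InvalidInputError(
            f"power spectrum has {power_spec.shape[1]} bins but filterbank expects "
            f"{filterbank.shape[1]}"
        )
    energies = power_spec @ filterbank.T
    return np.log(np.maximum(energies, log_floor))


def _dct_matrix(n: int) -> np.ndarray:
    # orthonormal DCT-II: C[k, j] = s_k * sqrt(2/n) * cos(pi * (2j + 1) * k / (2n))
    k = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    mat = np.sqrt(2.0 / n) * np.cos(np.pi * (2 * j + 1) * k / (2.0 * n))
    mat[0] /= np.sqrt(2.0)
    return mat


def dct_cepstra(log_mel: np.ndarray, n_coeffs: int) -> np.ndarray:
    """Orthonormal type-II DCT along the Mel axis, first n_coeffs retained."""
    log_mel = np.atleast_2d(log_mel)
    n_mels = log_mel.shape[1]
    if n_coeffs > n_mels:
        raise ConfigurationError(f"n_coeffs={n_coeffs} exceeds n_mels={n_mels}")
    return log_mel @ _dct_matrix(n_mels)[:n_coeffs].T


def extract_mfcc(signal: AudioSignal, cfg: MfccConfig | None = None) -> FeatureSequence:
    """Run the full MFCC chain; deterministic for fixed input and config."""
    cfg = cfg or MfccConfig()
    emphasized = preemphasize(signal, cfg.preemph)
    frames = frame_signal(emphasized, cfg)
    spec = power_spectrum(frames, cfg.n_fft)
    bank = mel_filterbank(cfg, signal.sample_rate)
    log_mel = log_mel_energies(spec, bank, cfg.log_floor)
    cepstra = dct_cepstra(log_mel, cfg.n_coeffs)
    hop = cfg.hop_length(signal.sample_rate)
    frame_times = hop * np.arange(cepstra.shape[0]) / signal.sample_rate
    return FeatureSequence(
        values=cepstra, frame_times=frame_times, sample_rate=signal.sample_rate, config=cfg
    )


def save_sequence_csv(seq: FeatureSequence, path) -> None:
    """Write a FeatureSequence as CSV: one row per frame, columns c00..cNN plus time_s."""
    header = ",".join([f"c{c:02d}" for c in range(seq.n_coeffs)] + ["time_s"])
    data = np.column_stack([seq.values, seq.frame_times])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def load_sequence_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a sequence CSV back as (values, frame_times)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return data[:, :-1], data[:, -1]


def functional_names(n_coeffs: int) -> tuple:
    return tuple(
        f"c{c:02d}_{stat}" for c in range(n_coeffs) for stat in FUNCTIONAL_NAMES
    )


def functionals(seq: FeatureSequence) -> FeatureVector:
    """Per-coefficient mean, sample sd, min and max, coefficient-major order."""
    v = seq.values
    if v.shape[0] < 2:
        raise InvalidInputError("at least 2 frames required (sample sd undefined)")
    stats = np.stack(
        [v.mean(axis=0), v.std(axis=0, ddof=1), v.min(axis=0), v.max(axis=0)], axis=1
    )  # (n_coeffs, 4)
    return FeatureVector(
        values=stats.reshape(-1), feature_names=functional_names(seq.n_coeffs)
    )
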