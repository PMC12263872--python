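"""Deterministic two-class synthetic data with known ground truth.

Audio: each recording is a harmonic stack whose fundamental is drawn from a
class-specific distribution, amplitude-modulated at a class-specific rate,
with randomly placed silent chunks covering a class-specific pause fraction,
plus additive Gaussian noise.  The two default classes differ in pitch
level, pitch variability, energy-modulation rate and pause fraction.

Tables: informative columns are Normal(+-delta/2, 1) by class, noise columns
Normal(0, 1) regardless of class; the ground-truth mask is returned.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io.wavfile

from .audio_features import AudioSignal
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "AudioClassParams",
    "TableParams",
    "CONTROL_CLASS",
    "CASE_CLASS",
    "generate_recording",
    "generate_audio_dataset",
    "write_audio_dataset",
    "generate_feature_table",
]


@dataclass(frozen=True)
class AudioClassParams:
    """Acoustic profile of one synthetic class."""

    f0_mean: float = 150.0  # Hz
    f0_sd: float = 15.0
    n_harmonics: int = 5
    energy_mod_rate: float = 3.0  # Hz
    pause_fraction: float = 0.2
    duration_s: float = 4.0
    noise_sd: float = 0.01
    sample_rate: int = 16000

    def __post_init__(self):
        if self.f0_mean <= 0:
            raise InvalidInputError("f0_mean must be positive")
        if not (0.0 <= self.pause_fraction < 1.0):
            raise InvalidInputError("pause_fraction must be in [0, 1)")
        if self.n_harmonics < 1 or self.duration_s <= 0 or self.sample_rate <= 0:
            raise InvalidInputError("invalid audio parameters")


CONTROL_CLASS = AudioClassParams(
    f0_mean=180.0, f0_sd=25.0, energy_mod_rate=5.0, pause_fraction=0.10
)
CASE_CLASS = AudioClassParams(
    f0_mean=120.0, f0_sd=8.0, energy_mod_rate=2.0, pause_fraction=0.35
)

_PAUSE_CHUNK_S = 0.1  # pauses are placed on a fixed 100 ms grid


@dataclass(frozen=True)
class TableParams:
    n_per_class: int = 200
    d: int = 30
    k: int = 5
    delta: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.k > self.d:
            raise ConfigurationError(f"k={self.k} informative features exceed d={self.d}")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if self.n_per_class < 1 or self.d < 1 or self.k < 0:
            raise ConfigurationError("invalid table parameters")


def generate_recording(params: AudioClassParams, rng: np.random.Generator) -> AudioSignal:
    """One synthetic voiced recording following the class profile."""
    sr = params.sample_rate
    n = int(round(params.duration_s * sr))
    t = np.arange(n) / sr
    f0 = max(20.0, rng.normal(params.f0_mean, params.f0_sd))
    voiced = np.zeros(n)
    for h in range(1, params.n_harmonics + 1):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        voiced += np.sin(2.0 * np.pi * h * f0 * t + phase) / h
    # energy modulation: raised cosine at the class modulation rate
    mod_phase = rng.uniform(0.0, 2.0 * np.pi)
    envelope = 0.5 * (1.0 + np.sin(2.0 * np.pi * params.energy_mod_rate * t + mod_phase))
    voiced *= 0.25 + 0.75 * envelope
    # silent chunks on a fixed grid covering the target pause fraction
    chunk = int(round(_PAUSE_CHUNK_S * sr))
    n_chunks = n // chunk
    n_silent = int(round(params.pause_fraction * n_chunks))
    if n_silent > 0:
        silent = rng.choice(n_chunks, size=n_silent, replace=False)
        for c in silent:
            voiced[c * chunk : (c + 1) * chunk] = 0.0
    peak = np.max(np.abs(voiced))
    if peak > 0:
        voiced *= 0.9 / peak
    samples = voiced + rng.normal(0.0, params.noise_sd, size=n)
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        samples /= peak
    return AudioSignal(samples=samples, sample_rate=sr)


def generate_audio_dataset(
    n_per_class: int,
    params_class0: AudioClassParams = CONTROL_CLASS,
    params_class1: AudioClassParams = CASE_CLASS,
    seed: int = 0,
):
    """Balanced labeled recordings, fully reproducible from the seed.

    Returns (signals, labels) with class 0 first.
    """
    rng = np.random.default_rng(seed)
    signals, labels = [], []
    for label, params in ((0, params_class0), (1, params_class1)):
        for _ in range(n_per_class):
            signals.append(generate_recording(params, rng))
            labels.append(label)
    return signals, np.array(labels, dtype=int)


def write_audio_dataset(out_dir, signals, labels) -> Path:
    """Write 16-bit PCM WAVs plus a (filename, label) CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (sig, label) in enumerate(zip(signals, labels)):
            name = f"rec_{i:04d}.wav"
            pcm = np.clip(sig.samples, -1.0, 1.0)
            scipy.io.wavfile.write(
                out_dir / name, sig.sample_rate, (pcm * 32767.0).astype(np.int16)
            )
            writer.writerow([name, int(label)])
    return manifest


def read_audio_manifest(manifest_path):
    """Read a (filename, label) manifest -> list of (path, label)."""
    manifest_path = Path(manifest_path)
    entries = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append((manifest_path.parent / row["filename"], int(row["label"])))
    if not entries:
        raise InvalidInputError(f"{manifest_path}: empty manifest")
    return entries


def generate_feature_table(params: TableParams):
    """Labeled Gaussian table with k informative columns.

    Returns (X, y, truth_mask) where truth_mask marks the informative columns
    (always the first k, with class-conditional means -delta/2 and +delta/2).
    """
    rng = np.random.default_rng(params.seed)
    n = 2 * params.n_per_class
    y = np.repeat([0, 1], params.n_per_class)
    X = rng.normal(0.0, 1.0, size=(n, params.d))
    shift = np.where(y == 1, params.delta / 2.0, -params.delta / 2.0)
    X[:, : params.k] += shift[:, None]
    truth = np.zeros(params.d, dtype=bool)
    truth[: params.k] = True
    return X, y, truth
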