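"""End-to-end orchestration: one validated config, one seed, one report.

The full run is: simulate (or load) audio -> MFCC extraction -> recording
level functionals -> stratified 60/20/20 split -> wrapper feature selection
on the training split only -> CNN-LSTM training on the mask-restricted
coefficient channels -> macro metrics on the untouched test split.

A functional mask is mapped onto MFCC channels by keeping every coefficient
with at least one selected functional, so the selector's verdict restricts
the sequence model's inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import audio_features, classifier, feature_selection, metrics, optimizers, synthetic_data
from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger("swarmspeech")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "load_config",
    "run_pipeline",
    "stratified_split",
    "functional_mask_to_coeff_mask",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MfccSection(_Section):
    frame_length_ms: float = 25.0
    hop_length_ms: float = 10.0
    n_fft: int = 512
    n_mels: int = 40
    n_coeffs: int = 13
    preemph: float = 0.97
    fmin: float = 0.0
    fmax: float = 8000.0
    log_floor: float = 1e-10

    def to_config(self) -> audio_features.MfccConfig:
        return audio_features.MfccConfig(**self.model_dump())


class OptimizerSection(_Section):
    kind: Literal["dragonfly", "firefly", "mothflame"] = "firefly"
    pop_size: int = 50
    n_iter: int = 200
    # dragonfly
    alpha_start: float = 1.0
    alpha_end: float = 0.1
    beta: float = 0.5
    # firefly
    alpha: float = 0.2
    beta0: float = 1.0
    gamma: float = 1.0
    # moth-flame
    b: float = 1.0

    def to_config(self):
        if self.kind == "dragonfly":
            return optimizers.DAConfig(
                pop_size=self.pop_size,
                n_iter=self.n_iter,
                alpha_start=self.alpha_start,
                alpha_end=self.alpha_end,
                beta=self.beta,
            )
        if self.kind == "firefly":
            return optimizers.FAConfig(
                pop_size=self.pop_size,
                n_iter=self.n_iter,
                alpha=self.alpha,
                beta0=self.beta0,
                gamma=self.gamma,
            )
        return optimizers.MFOConfig(pop_size=self.pop_size, n_iter=self.n_iter, b=self.b)


class SelectionSection(_Section):
    sparsity_weight: float = 0.01
    threshold: float = 0.5
    surrogate: Literal["linear", "cnn_lstm"] = "linear"
    cv_folds: int = 3


class ModelSection(_Section):
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 5
    pool_size: int = 2
    dropout_rate: float = 0.3
    temporal_pool_factor: int = 4
    lstm_units: tuple[int, int] = (64, 32)
    dense_units: int = 32
    t_fixed: int = 512
    literal_gap: bool = False


class TrainingSection(_Section):
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stop_patience: int = 8
    class_weighting: bool = True


class SimulateSection(_Section):
    n_per_class: int = 60
    class0: dict = Field(default_factory=dict)
    class1: dict = Field(default_factory=dict)

    def class_params(self):
        p0 = dataclasses.replace(synthetic_data.CONTROL_CLASS, **self.class0)
        p1 = dataclasses.replace(synthetic_data.CASE_CLASS, **self.class1)
        return p0, p1


class IoSection(_Section):
    audio_manifest: Optional[str] = None  # read recordings from here instead of simulating
    out_dir: str = "swarmspeech_run"


class PipelineConfig(_Section):
    seed: int = 0
    mfcc: MfccSection = Field(default_factory=MfccSection)
    optimizer: OptimizerSection = Field(default_factory=OptimizerSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    io: IoSection = Field(default_factory=IoSection)


@dataclasses.dataclass(frozen=True)
class RunReport:
    config: dict
    selected_features: tuple
    selected_coeffs: tuple
    metrics: metrics.Metrics
    fitness_history: np.ndarray
    wall_clock_s: float
    artifact_paths: dict

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "selected_features": list(self.selected_features),
            "selected_coeffs": list(self.selected_coeffs),
            "metrics": {
                "macro_precision": self.metrics.macro_precision,
                "macro_recall": self.metrics.macro_recall,
                "macro_f1": self.metrics.macro_f1,
                "per_class": {
                    str(label): dict(zip(("precision", "recall", "f1"), values))
                    for label, values in self.metrics.per_class.items()
                },
            },
            "fitness_history": [float(v) for v in self.fitness_history],
            "wall_clock_s": self.wall_clock_s,
            "artifact_paths": {k: str(v) for k, v in self.artifact_paths.items()},
        }
        return json.dumps(payload, indent=2)


def load_config(path) -> PipelineConfig:
    """Parse a YAML config file; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def stratified_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Per-class shuffled index split into train/validation/test."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts = ([], [], [])
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def functional_mask_to_coeff_mask(mask: feature_selection.FeatureMask, n_coeffs: int) -> np.ndarray:
    """Keep every coefficient that has at least one selected functional."""
    n_funcs = len(audio_features.FUNCTIONAL_NAMES)
    if mask.selected.size != n_coeffs * n_funcs:
        raise InvalidInputError(
            f"mask length {mask.selected.size} != {n_coeffs} coeffs x {n_funcs} functionals"
        )
    coeff_mask = mask.selected.reshape(n_coeffs, n_funcs).any(axis=1)
    if not coeff_mask.any():
        coeff_mask[0] = True
    return coeff_mask


def _load_or_simulate_audio(cfg: PipelineConfig):
    if cfg.io.audio_manifest:
        entries = synthetic_data.read_audio_manifest(cfg.io.audio_manifest)
        signals = [audio_features.load_wav(path) for path, _ in entries]
        labels = np.array([label for _, label in entries], dtype=int)
        logger.info("loaded %d recordings from %s", len(signals), cfg.io.audio_manifest)
    else:
        p0, p1 = cfg.simulate.class_params()
        signals, labels = synthetic_data.generate_audio_dataset(
            cfg.simulate.n_per_class, p0, p1, seed=cfg.seed
        )
        logger.info("simulated %d recordings per class", cfg.simulate.n_per_class)
    return signals, labels


def run_pipeline(cfg: PipelineConfig, mask_path=None) -> RunReport:
    """Execute the full extract -> select -> train -> evaluate pipeline.

    If ``mask_path`` names an existing functional-mask file, the selection
    stage is skipped and that mask is used as-is.
    """
    t0 = time.perf_counter()
    out_dir = Path(cfg.io.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        signals, labels = _load_or_simulate_audio(cfg)

        stage = "extract"
        mfcc_cfg = cfg.mfcc.to_config()
        sequences = [audio_features.extract_mfcc(sig, mfcc_cfg) for sig in signals]
        vectors = [audio_features.functionals(seq) for seq in sequences]
        table = np.stack([v.values for v in vectors])
        feature_names = vectors[0].feature_names
        logger.info("extracted %d-frame MFCC sequences, %d functionals", sequences[0].n_frames, table.shape[1])

        stage = "split"
        train_idx, val_idx, test_idx = stratified_split(labels, seed=cfg.seed)

        stage = "select"
        if mask_path is not None:
            best_mask = feature_selection.load_mask(mask_path, feature_names)
            selection = feature_selection.SelectionResult(
                best_mask=best_mask,
                best_fitness=float("nan"),
                history=np.empty(0),
                selection_frequency=best_mask.selected.astype(float),
                feature_names=feature_names,
            )
            logger.info("using precomputed mask from %s", mask_path)
        else:
            sel_cfg = feature_selection.SelectionConfig(
                optimizer_kind=cfg.optimizer.kind,
                optimizer_config=cfg.optimizer.to_config(),
                sparsity_weight=cfg.selection.sparsity_weight,
                threshold=cfg.selection.threshold,
                surrogate=cfg.selection.surrogate,
                cv_folds=cfg.selection.cv_folds,
                seed=cfg.seed,
            )
            selection = feature_selection.select_features(
                table[train_idx], labels[train_idx], sel_cfg, feature_names=feature_names
            )
            logger.info(
                "selected %d/%d functionals, fitness %.4f",
                selection.best_mask.n_selected, table.shape[1], selection.best_fitness,
            )

        stage = "train"
        coeff_mask = functional_mask_to_coeff_mask(selection.best_mask, mfcc_cfg.n_coeffs)
        t_fixed = cfg.model.t_fixed
        stacked = np.stack(
            [classifier.pad_or_truncate(seq.values[:, coeff_mask], t_fixed) for seq in sequences]
        )
        spec = classifier.ModelSpec(
            conv_filters=tuple(cfg.model.conv_filters),
            kernel_size=cfg.model.kernel_size,
            pool_size=cfg.model.pool_size,
            dropout_rate=cfg.model.dropout_rate,
            temporal_pool_factor=cfg.model.temporal_pool_factor,
            lstm_units=tuple(cfg.model.lstm_units),
            dense_units=cfg.model.dense_units,
            input_shape=(t_fixed, int(coeff_mask.sum())),
            literal_gap=cfg.model.literal_gap,
        )
        train_cfg = classifier.TrainConfig(
            epochs=cfg.training.epochs,
            batch_size=cfg.training.batch_size,
            learning_rate=cfg.training.learning_rate,
            early_stop_patience=cfg.training.early_stop_patience,
            seed=cfg.seed,
            class_weighting=cfg.training.class_weighting,
        )
        model = classifier.build_model(spec, seed=cfg.seed)
        trained = classifier.train(
            model,
            (stacked[train_idx], labels[train_idx]),
            (stacked[val_idx], labels[val_idx]),
            train_cfg,
        )

        stage = "evaluate"
        y_pred, _ = classifier.predict(trained, stacked[test_idx])
        result = metrics.macro_metrics(labels[test_idx], y_pred)
        logger.info("held-out macro F1 %.4f", result.macro_f1)
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        raise

    artifacts = {}
    mask_path = out_dir / "selected_features.txt"
    feature_selection.save_mask(mask_path, selection)
    artifacts["mask"] = mask_path
    history_path = out_dir / "fitness_history.csv"
    np.savetxt(
        history_path,
        np.column_stack([np.arange(len(selection.history)), selection.history]),
        delimiter=",",
        header="iteration,best_fitness",
        comments="",
    )
    artifacts["fitness_history"] = history_path
    report = RunReport(
        config=cfg.model_dump(),
        selected_features=selection.selected_names,
        selected_coeffs=tuple(int(i) for i in np.flatnonzero(coeff_mask)),
        metrics=result,
        fitness_history=selection.history,
        wall_clock_s=time.perf_counter() - t0,
        artifact_paths=artifacts,
    )
    report_path = out_dir / "report.json"
    report_path.write_text(report.to_json())
    artifacts["report"] = report_path
    return report
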