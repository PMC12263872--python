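"""Wrapper feature selection driven by the swarm optimizers.

A candidate subset is a continuous position in [0, 1]^d; coordinates at or
above a threshold select the matching feature (with an argmax rescue so the
mask is never empty).  A mask is scored by stratified cross-validated macro
F1 of a surrogate classifier on the masked columns, penalized by the
selected-feature ratio:

    fitness(mask) = (1 - macroF1_cv) + sparsity_weight * n_selected / d

Lower is better.  The cross-validation folds are seeded from the run seed,
so fitness is a pure function of (mask, table, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import optimizers
from .errors import ConfigurationError, InvalidInputError
from .metrics import macro_metrics

__all__ = [
    "FeatureMask",
    "SelectionConfig",
    "SelectionResult",
    "decode_mask",
    "fitness",
    "select_features",
]

SURROGATES = ("linear", "cnn_lstm")


@dataclass(frozen=True)
class FeatureMask:
    """Boolean vector over feature indices."""

    selected: np.ndarray

    def __post_init__(self):
        sel = np.asarray(self.selected, dtype=bool)
        if sel.ndim != 1 or sel.size == 0:
            raise InvalidInputError("mask must be a non-empty 1-D boolean vector")
        object.__setattr__(self, "selected", sel)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    def key(self) -> bytes:
        return np.packbits(self.selected).tobytes()


@dataclass(frozen=True)
class SelectionConfig:
    optimizer_kind: str = "firefly"
    optimizer_config: object = None  # DAConfig / FAConfig / MFOConfig; kind defaults if None
    sparsity_weight: float = 0.01
    threshold: float = 0.5
    surrogate: str = "linear"
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.optimizer_kind not in optimizers.OPTIMIZER_KINDS:
            raise ConfigurationError(
                f"unknown optimizer_kind {self.optimizer_kind!r}"
            )
        if self.sparsity_weight < 0:
            raise ConfigurationError("sparsity_weight must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.surrogate not in SURROGATES:
            raise ConfigurationError(f"surrogate must be one of {SURROGATES}")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass(frozen=True)
class SelectionResult:
    best_mask: FeatureMask
    best_fitness: float
    history: np.ndarray  # per-iteration best fitness
    selection_frequency: np.ndarray  # per-feature frequency across final population
    feature_names: tuple | None = None

    @property
    def selected_names(self) -> tuple:
        if self.feature_names is None:
            return tuple(str(i) for i in self.best_mask.indices)
        return tuple(self.feature_names[i] for i in self.best_mask.indices)


def decode_mask(position, threshold: float) -> FeatureMask:
    """Threshold a continuous position into a mask; argmax rescue if empty."""
    pos = np.asarray(position, dtype=np.float64)
    selected = pos >= threshold
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(pos))] = True
    return FeatureMask(selected=selected)


def _validate_table(X, y, mask: FeatureMask | None = None):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise InvalidInputError("feature table must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError("feature table and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")
    if mask is not None and mask.selected.size != X.shape[1]:
        raise InvalidInputError(
            f"mask length {mask.selected.size} != table width {X.shape[1]}"
        )
    return X, y.astype(int)


def _surrogate_cv_macro_f1(X_masked, y, cfg: SelectionConfig) -> float:
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X_masked, y):
        if cfg.surrogate == "linear":
            clf = make_pipeline(
                StandardScaler(),
                LogisticRegression(C=1.0, max_iter=1000, random_state=cfg.seed),
            )
            clf.fit(X_masked[train_idx], y[train_idx])
            y_pred[test_idx] = clf.predict(X_masked[test_idx])
        else:  # cnn_lstm: table rows treated as length-d single-channel sequences
            from .classifier import ModelSpec, TrainConfig, build_model, train, predict

            d = X_masked.shape[1]
            spec = ModelSpec(
                conv_filters=(4, 6, 8),
                kernel_size=3,
                pool_size=1,
                dropout_rate=0.0,
                temporal_pool_factor=1,
                lstm_units=(8, 4),
                dense_units=8,
                input_shape=(d, 1),
            )
            model = build_model(spec, seed=cfg.seed)
            seqs = X_masked[:, :, None]
            trained = train(
                model,
                (seqs[train_idx], y[train_idx]),
                (seqs[test_idx], y[test_idx]),
                TrainConfig(epochs=10, batch_size=16, seed=cfg.seed),
            )
            y_pred[test_idx], _ = predict(trained, seqs[test_idx])
    return macro_metrics(y, y_pred).macro_f1


def fitness(mask: FeatureMask, X, y, cfg: SelectionConfig) -> float:
    """(1 - cross-validated macro F1) + sparsity_weight * selected ratio."""
    X, y = _validate_table(X, y, mask)
    if mask.n_selected < 1:
        raise InvalidInputError("mask must select at least one feature")
    macro_f1 = _surrogate_cv_macro_f1(X[:, mask.selected], y, cfg)
    return (1.0 - macro_f1) + cfg.sparsity_weight * mask.n_selected / mask.selected.size


def select_features(X, y, cfg: SelectionConfig | None = None, feature_names=None) -> SelectionResult:
    """Run swarm search over [0, 1]^d masks; returns the decoded best subset.

    Fitness values are cached per mask, so re-visited subsets cost nothing.
    """
    cfg = cfg or SelectionConfig()
    X, y = _validate_table(X, y)
    d = X.shape[1]
    if d < 2:
        raise InvalidInputError("need at least 2 features to select from")
    cache: dict[bytes, float] = {}

    def objective(position):
        mask = decode_mask(position, cfg.threshold)
        key = mask.key()
        if key not in cache:
            cache[key] = fitness(mask, X, y, cfg)
        return cache[key]

    bounds = np.tile([0.0, 1.0], (d, 1))
    opt_cfg = cfg.optimizer_config
    result = optimizers.optimize(
        objective, bounds, cfg.optimizer_kind, config=opt_cfg, seed=cfg.seed
    )
    best_mask = decode_mask(result.best_position, cfg.threshold)
    final_masks = np.stack(
        [decode_mask(p, cfg.threshold).selected for p in result.final_positions]
    )
    freq = final_masks.mean(axis=0)
    return SelectionResult(
        best_mask=best_mask,
        best_fitness=float(result.best_fitness),
        history=result.history,
        selection_frequency=freq,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


# ---------------------------------------------------------------------------
# delimited-table and mask-file interchange


def save_feature_table(path, X, y, feature_names) -> None:
    """Write a CSV feature table; final column is named ``label``."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(X, dtype=np.float64), columns=list(feature_names))
    df["label"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False)


def load_feature_table(path):
    """Read a CSV feature table -> (X, y, feature_names)."""
    import pandas as pd

    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"{path}: feature table must have a 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=np.float64), y, tuple(df.columns)


def save_mask(path, result: SelectionResult) -> None:
    """Write the selected feature names, one per line."""
    with open(path, "w") as fh:
        for name in result.selected_names:
            fh.write(f"{name}\n")


def load_mask(path, feature_names) -> FeatureMask:
    """Read a mask file (one feature name per line) against a name list."""
    with open(path) as fh:
        chosen = {line.strip() for line in fh if line.strip()}
    names = list(feature_names)
    unknown = chosen - set(names)
    if unknown:
        raise InvalidInputError(f"{path}: unknown feature names {sorted(unknown)}")
    return FeatureMask(selected=np.array([n in chosen for n in names]))
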