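"""CNN-LSTM binary classifier: architecture spec, training loop, inference.

Layer order: [Conv1D+ReLU -> MaxPool -> Dropout -> BatchNorm] x 3 with
strictly increasing filter counts, then a sequence-preserving temporal
average pooling (or a literal global pool feeding the LSTMs a length-1
sequence when ``literal_gap`` is set), two LSTM layers (the second keeping
only its final state), a ReLU dense layer, and a single output unit.  The
output head produces a logit; probabilities are sigmoid(logit).

Training minimizes class-weighted binary cross-entropy with Adam, early
stops on validation macro F1 and restores the best-validation checkpoint.
All randomness (init, shuffling, dropout) flows from explicit seeds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, InvalidInputError
from ..metrics import macro_metrics
from .layers import (
    Adam,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    GlobalAvgPool,
    LSTM,
    MaxPool1D,
    ReLU,
    TemporalAvgPool,
    sigmoid,
)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "CnnLstmModel",
    "pad_or_truncate",
    "build_model",
    "train",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    conv_filters: tuple = (32, 64, 128)
    kernel_size: int = 5
    pool_size: int = 2
    dropout_rate: float = 0.3
    temporal_pool_factor: int = 4
    lstm_units: tuple = (64, 32)
    dense_units: int = 32
    input_shape: tuple = (512, 13)  # (T_fixed, n_channels)
    literal_gap: bool = False

    def __post_init__(self):
        if len(self.conv_filters) != 3 or list(self.conv_filters) != sorted(
            set(self.conv_filters)
        ):
            raise ConfigurationError("conv_filters must be three strictly increasing counts")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if len(self.lstm_units) != 2:
            raise ConfigurationError("lstm_units must have exactly two entries")
        if min(self.kernel_size, self.pool_size, self.temporal_pool_factor, self.dense_units) < 1:
            raise ConfigurationError("layer size parameters must be positive")
        t, c = self.input_shape
        if t < self.pool_size**3 or c < 1:
            raise ConfigurationError(f"input_shape {self.input_shape} too small for the conv stack")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stop_patience: int = 8
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigurationError("invalid training configuration")
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be >= 1")


class CnnLstmModel:
    """The assembled network; holds layers and its own dropout RNG."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        t, channels = spec.input_shape
        layers = []
        in_ch = channels
        for filters in spec.conv_filters:
            layers.append(Conv1D(in_ch, filters, spec.kernel_size, rng))
            layers.append(ReLU())
            layers.append(MaxPool1D(spec.pool_size))
            layers.append(Dropout(spec.dropout_rate, self.dropout_rng))
            layers.append(BatchNorm1D(filters))
            in_ch = filters
        if spec.literal_gap:
            layers.append(GlobalAvgPool())
        else:
            layers.append(TemporalAvgPool(spec.temporal_pool_factor))
        layers.append(LSTM(in_ch, spec.lstm_units[0], rng, return_sequences=True))
        layers.append(LSTM(spec.lstm_units[0], spec.lstm_units[1], rng, return_sequences=False))
        layers.append(Dense(spec.lstm_units[1], spec.dense_units, rng, activation="relu"))
        layers.append(Dense(spec.dense_units, 1, rng, activation=None))
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x, training: bool = False) -> np.ndarray:
        """Logits for a batch of (T, C) sequences."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise InvalidInputError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, 0]

    def backward(self, grad_logit):
        grad = grad_logit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x) -> np.ndarray:
        return sigmoid(self.forward(x, training=False))

    def get_weights(self):
        state = [copy.deepcopy(self.params)]
        state.append(
            [
                (layer.running_mean.copy(), layer.running_var.copy())
                for layer in self.layers
                if isinstance(layer, BatchNorm1D)
            ]
        )
        return state

    def set_weights(self, state):
        for p, saved in zip(self.params, state[0]):
            p[...] = saved
        bn_layers = [layer for layer in self.layers if isinstance(layer, BatchNorm1D)]
        for layer, (mean, var) in zip(bn_layers, state[1]):
            layer.running_mean = mean.copy()
            layer.running_var = var.copy()


@dataclass
class TrainedModel:
    model: CnnLstmModel
    history: list  # (epoch, train_loss, val_macro_f1) tuples
    spec: ModelSpec


def pad_or_truncate(values, t_fixed: int) -> np.ndarray:
    """Fix a (T, C) sequence to exactly (t_fixed, C).

    Longer sequences are centre-cropped (floor offset); shorter ones are
    zero-padded at the end.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] == 0:
        raise InvalidInputError("sequence must be a non-empty (T, C) matrix")
    t = values.shape[0]
    if t == t_fixed:
        return values.copy()
    if t > t_fixed:
        offset = (t - t_fixed) // 2
        return values[offset : offset + t_fixed].copy()
    out = np.zeros((t_fixed, values.shape[1]))
    out[:t] = values
    return out


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> CnnLstmModel:
    """Seeded construction; identical spec and seed give identical parameters."""
    return CnnLstmModel(spec or ModelSpec(), seed=seed)


def _stack(sequences, spec: ModelSpec) -> np.ndarray:
    t_fixed, channels = spec.input_shape
    arr = np.asarray(sequences, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[1:] != (t_fixed, channels):
        raise InvalidInputError(
            f"sequences must have shape (n, {t_fixed}, {channels}); got {arr.shape}"
        )
    return arr


def train(model: CnnLstmModel, train_set, validation_set, cfg: TrainConfig | None = None) -> TrainedModel:
    """Fit with class-weighted BCE; early-stop and checkpoint on validation macro F1."""
    cfg = cfg or TrainConfig()
    x_train, y_train = train_set
    x_val, y_val = validation_set
    x_train = _stack(x_train, model.spec)
    x_val = _stack(x_val, model.spec)
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=int)
    classes, counts = np.unique(y_train.astype(int), return_counts=True)
    if len(classes) < 2:
        raise InvalidInputError("training set must contain both classes")
    if cfg.class_weighting:
        weight_by_class = {c: y_train.size / (2.0 * n) for c, n in zip(classes, counts)}
    else:
        weight_by_class = {0: 1.0, 1: 1.0}
    sample_w = np.array([weight_by_class[int(label)] for label in y_train])

    history = []
    if cfg.epochs == 0:
        return TrainedModel(model=model, history=history, spec=model.spec)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.params, lr=cfg.learning_rate)
    best_state = model.get_weights()
    best_f1 = -np.inf
    stale = 0
    n = x_train.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb, wb = x_train[idx], y_train[idx], sample_w[idx]
            logits = model.forward(xb, training=True)
            probs = sigmoid(logits)
            eps = 1e-12
            loss = -np.mean(
                wb * (yb * np.log(probs + eps) + (1.0 - yb) * np.log(1.0 - probs + eps))
            )
            model.backward(wb * (probs - yb) / len(idx))
            optimizer.step(model.grads)
            losses.append(loss)
        val_pred = (predict_proba_batched(model, x_val) >= 0.5).astype(int)
        val_f1 = macro_metrics(y_val, val_pred).macro_f1 if len(np.unique(y_val)) > 1 else 0.0
        history.append((epoch, float(np.mean(losses)), float(val_f1)))
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_state = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    model.set_weights(best_state)
    return TrainedModel(model=model, history=history, spec=model.spec)


def predict_proba_batched(model: CnnLstmModel, x, batch_size: int = 32) -> np.ndarray:
    x = _stack(x, model.spec)
    return np.concatenate(
        [model.predict_proba(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    )


def predict(trained, sequences):
    """(labels, probabilities); label = probability >= 0.5."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    probs = predict_proba_batched(model, sequences)
    return (probs >= 0.5).astype(int), probs


def save_model(trained, path) -> None:
    """Checkpoint spec + weights + BN statistics (NumPy .npz container)."""
    import dataclasses
    import json

    model = trained.model if isinstance(trained, TrainedModel) else trained
    state = model.get_weights()
    arrays = {f"param_{i}": p for i, p in enumerate(state[0])}
    for i, (mean, var) in enumerate(state[1]):
        arrays[f"bn_mean_{i}"] = mean
        arrays[f"bn_var_{i}"] = var
    spec_dict = dataclasses.asdict(model.spec)
    spec_dict["conv_filters"] = list(spec_dict["conv_filters"])
    spec_dict["lstm_units"] = list(spec_dict["lstm_units"])
    spec_dict["input_shape"] = list(spec_dict["input_shape"])
    arrays["spec_json"] = np.frombuffer(json.dumps(spec_dict).encode(), dtype=np.uint8)
    arrays["seed"] = np.array(model.seed)
    np.savez(path, **arrays)


def load_model(path) -> CnnLstmModel:
    """Rebuild a checkpointed model; inference output is bit-identical."""
    import json

    with np.load(path) as data:
        spec_dict = json.loads(bytes(data["spec_json"]).decode())
        spec_dict["conv_filters"] = tuple(spec_dict["conv_filters"])
        spec_dict["lstm_units"] = tuple(spec_dict["lstm_units"])
        spec_dict["input_shape"] = tuple(spec_dict["input_shape"])
        model = CnnLstmModel(ModelSpec(**spec_dict), seed=int(data["seed"]))
        params = [data[f"param_{i}"] for i in range(len(model.params))]
        n_bn = sum(1 for layer in model.layers if isinstance(layer, BatchNorm1D))
        bn = [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)]
    model.set_weights([params, bn])
    return model


def export_history(trained: TrainedModel, path) -> None:
    """Training history as delimited text: epoch, loss, val_macro_f1."""
    rows = np.array(trained.history, dtype=np.float64).reshape(-1, 3)
    np.savetxt(path, rows, delimiter=",", header="epoch,loss,val_macro_f1", comments="")
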