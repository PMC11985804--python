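"""The seven classifier architectures and the evaluation protocol.

Three multilayer perceptrons, a simple RNN, an LSTM, a GRU and a hybrid
CNN-LSTM map an 855-dimensional connectivity feature vector (or its
metric-concatenated variants) to four consciousness-state probabilities.
Sequence models consume the natural band-major factorization of the feature
vector: 5 time steps (delta..gamma), 171 pair features per step and per
metric. Evaluation reports accuracy and support-weighted precision, recall
and F1, with percentile-bootstrap 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (confusion_matrix as _sk_confusion,
                             precision_recall_fscore_support)

from .nn import (Adam, BatchNorm, Conv1D, Dense, Dropout, GRU, History, LSTM,
                 MaxPool1D, ReLU, Sequential, SimpleRNN)
from .types import CLASS_ORDER

ARCHITECTURES = ("mlp1", "mlp2", "mlp3", "rnn", "lstm", "gru", "cnn_lstm")
_SEQUENCE_ARCHS = ("rnn", "lstm", "gru", "cnn_lstm")


@dataclass
class ModelSpec:
    """Resolved training configuration for one architecture."""

    arch_id: str
    input_dim: int
    n_classes: int = 4
    n_metrics: int = 1          # sequence reshape: (5, n_metrics * n_pairs)
    n_bands: int = 5
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    validation_split: float = 0.1
    early_stopping_patience: int | None = None
    reduce_lr_patience: int | None = None
    seed: int = 0

    @property
    def is_sequence(self) -> bool:
        return self.arch_id in _SEQUENCE_ARCHS

    def reshape(self, X: np.ndarray) -> np.ndarray:
        """Flat features -> (batch, bands, features-per-band) for sequences."""
        if not self.is_sequence:
            return X
        n, d = X.shape
        per_metric = d // self.n_metrics
        pairs = per_metric // self.n_bands
        # columns are metric-major then band-major; stack metrics on the
        # feature axis so time steps remain the 5 bands
        parts = [X[:, m * per_metric:(m + 1) * per_metric]
                 .reshape(n, self.n_bands, pairs)
                 for m in range(self.n_metrics)]
        return np.concatenate(parts, axis=2)


def build_model(arch_id: str, input_dim: int, seed: int = 0,
                n_metrics: int = 1, n_classes: int = 4,
                n_bands: int = 5) -> tuple[Sequential, ModelSpec]:
    """Instantiate one of the seven architectures.

    Layer plans, dropout rates, L2 penalties, optimizers and epoch budgets
    follow the published model descriptions; unknown ``arch_id`` raises.
    """
    if arch_id not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch_id!r}")
    rng = np.random.default_rng(seed)
    spec = ModelSpec(arch_id=arch_id, input_dim=input_dim,
                     n_classes=n_classes, n_metrics=n_metrics,
                     n_bands=n_bands, seed=seed)
    seq_features = (input_dim // n_metrics // n_bands) * n_metrics

    if arch_id == "mlp1":
        layers = [
            Dense(input_dim, 128, rng), ReLU(), Dropout(0.5, rng),
            Dense(128, 64, rng), ReLU(), Dropout(0.3, rng),
            Dense(64, n_classes, rng),
        ]
        spec.lr, spec.epochs = 1e-3, 50
    elif arch_id == "mlp2":
        layers = [
            Dense(input_dim, 256, rng), ReLU(), BatchNorm(256),
            Dropout(0.4, rng),
            Dense(256, 128, rng, l2=1e-3), ReLU(), BatchNorm(128),
            Dropout(0.4, rng),
            Dense(128, 64, rng, l2=1e-3), ReLU(), Dropout(0.3, rng),
            Dense(64, n_classes, rng),
        ]
        spec.lr, spec.epochs = 1e-3, 100
    elif arch_id == "mlp3":
        layers = [
            Dense(input_dim, 256, rng, l2=1e-3), ReLU(), BatchNorm(256),
            Dropout(0.4, rng),
            Dense(256, 128, rng, l2=1e-3), ReLU(), BatchNorm(128),
            Dropout(0.4, rng),
            Dense(128, n_classes, rng),
        ]
        spec.lr, spec.epochs = 1e-3, 60
        spec.early_stopping_patience, spec.reduce_lr_patience = 10, 5
    elif arch_id in ("rnn", "lstm", "gru"):
        cell = {"rnn": SimpleRNN, "lstm": LSTM, "gru": GRU}[arch_id]
        layers = [
            cell(seq_features, 128, rng, return_sequences=True),
            Dropout(0.4, rng), BatchNorm(128),
            cell(128, 64, rng, return_sequences=False),
            Dropout(0.3, rng), BatchNorm(64),
            Dense(64, 32, rng), ReLU(), Dropout(0.2, rng),
            Dense(32, n_classes, rng),
        ]
        spec.lr, spec.epochs = 5e-4, 50
        if arch_id in ("lstm", "gru"):
            spec.early_stopping_patience, spec.reduce_lr_patience = 10, 5
    else:  # cnn_lstm
        layers = [
            Conv1D(seq_features, 64, 3, rng), ReLU(), BatchNorm(64),
            MaxPool1D(2),
            Conv1D(64, 128, 3, rng), ReLU(), BatchNorm(128),
            MaxPool1D(2),
            LSTM(128, 64, rng, return_sequences=True), Dropout(0.3, rng),
            LSTM(64, 32, rng, return_sequences=False), Dropout(0.2, rng),
            Dense(32, 32, rng), ReLU(), Dropout(0.2, rng),
            Dense(32, n_classes, rng),
        ]
        spec.lr, spec.epochs = 5e-4, 50
        spec.early_stopping_patience, spec.reduce_lr_patience = 10, 5
    return Sequential(layers), spec


def train(model: Sequential, spec: ModelSpec, X: np.ndarray, Y: np.ndarray,
          epochs: int | None = None) -> History:
    """Train on standardized inputs and one-hot targets per the spec."""
    Xf = spec.reshape(np.asarray(X, dtype=np.float64))
    if Y.ndim != 2:
        raise ValueError("targets must be one-hot encoded")
    return model.fit(
        Xf, Y, epochs=epochs or spec.epochs, batch_size=spec.batch_size,
        validation_split=spec.validation_split,
        optimizer=Adam(lr=spec.lr), seed=spec.seed,
        early_stopping_patience=spec.early_stopping_patience,
        reduce_lr_patience=spec.reduce_lr_patience,
    )


@dataclass
class CI:
    """A point estimate with a bootstrap interval: lower <= point <= upper."""

    point: float
    lower: float
    upper: float


def confidence_interval(values: np.ndarray, level: float = 0.95,
                        n_boot: int = 1000, seed: int = 0) -> CI:
    """Percentile bootstrap over per-sample values (e.g. correctness)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty input")
    if values.size < 2:
        v = float(values.mean())
        return CI(point=v, lower=v, upper=v)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    point = float(values.mean())
    return CI(point=point, lower=float(min(lo, point)),
              upper=float(max(hi, point)))


@dataclass
class EvalReport:
    """Test-set evaluation: weighted metrics, confusion matrix, 95% CIs."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    class_order: tuple[str, ...]
    ci: dict[str, CI] = field(default_factory=dict)
    history: History | None = None
    n_test: int = 0

    def summary(self) -> str:
        lines = [f"n_test = {self.n_test}"]
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            c = self.ci.get(name)
            tail = f"  (95% CI {c.lower:.3f}-{c.upper:.3f})" if c else ""
            lines.append(f"{name:>9}: {v:.3f}{tail}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "n_test": self.n_test,
            "ci": {k: asdict(v) for k, v in self.ci.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate(model: Sequential, spec: ModelSpec, X: np.ndarray,
             Y: np.ndarray, class_order: tuple[str, ...] = CLASS_ORDER,
             ci_seed: int = 0, history: History | None = None,
             n_boot: int = 1000) -> EvalReport:
    """Weighted-average metrics over the four classes plus bootstrap CIs.

    Precision/recall/F1 CIs resample (true, predicted) pairs; the accuracy CI
    resamples per-sample correctness.
    """
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    y_true = np.argmax(Y, axis=1)
    y_pred = model.predict_classes(spec.reshape(np.asarray(X, float)))
    labels = np.arange(len(class_order))
    acc = float((y_true == y_pred).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0)
    conf = _sk_confusion(y_true, y_pred, labels=labels)

    ci = {"accuracy": confidence_interval(
        (y_true == y_pred).astype(float), seed=ci_seed, n_boot=n_boot)}
    rng = np.random.default_rng(ci_seed + 1)
    n = len(y_true)
    boot = {"precision": [], "recall": [], "f1": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        p, r, f, _ = precision_recall_fscore_support(
            y_true[idx], y_pred[idx], labels=labels, average="weighted",
            zero_division=0)
        boot["precision"].append(p)
        boot["recall"].append(r)
        boot["f1"].append(f)
    for name, point in (("precision", prec), ("recall", rec), ("f1", f1)):
        lo, hi = np.quantile(boot[name], [0.025, 0.975])
        ci[name] = CI(point=float(point), lower=float(min(lo, point)),
                      upper=float(max(hi, point)))
    return EvalReport(accuracy=acc, precision=float(prec), recall=float(rec),
                      f1=float(f1), confusion=conf, class_order=class_order,
                      ci=ci, history=history, n_test=n)
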