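"""The 8-class feed-forward neural classifier.

Architecture: 94 inputs, three hidden tanh layers of 50, 10 and 20
neurons, softmax output over the eight sub-technique classes.  Training
uses L2-regularized backpropagation (scikit-learn's MLPClassifier with the
deterministic L-BFGS solver); because the loss surface is non-convex the
network is trained from several random initializations (20 by default) and
the restart with the best validation accuracy is kept (ties broken by
lower validation cross-entropy, then lower restart index).  The
regularization strength cycles through a small grid across restarts, so
the grid is also selected on the validation set without multiplying the
fit count.

Feature standardization (z-scoring with training-set statistics) happens
inside the model: the persisted JSON carries the per-feature mean and
standard deviation, and prediction applies them before the forward pass,
so raw 94-element feature vectors are always the outward interface.

Two surfaces are provided: plain :func:`train` / ``MlpModel.predict``
functions, and a statsmodels-style pair — :class:`SubTechniqueClassifier`
(a model bound to its training and validation data) whose ``fit()``
returns a :class:`ClassifierFit` results object with per-restart
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from . import cycles as _cycles
from . import features as _features
from . import preprocessing as _pre
from .evaluation import ConfusionMatrix, build_confusion
from .io import CLASSES, Cycle, ImuSeries, SubTechnique

__all__ = [
    "HIDDEN_LAYERS",
    "TrainConfig",
    "MlpModel",
    "RestartRecord",
    "train",
    "predict",
    "classify_session",
    "SubTechniqueClassifier",
    "ClassifierFit",
]

#: Hidden-layer widths of the classifier network.
HIDDEN_LAYERS = (50, 10, 20)

_MODEL_FORMAT = "skitech-mlp"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``restarts`` independent random initializations are run; restart ``r``
    uses L2 strength ``alpha_grid[r % len(alpha_grid)]``.  ``max_iter``
    bounds the L-BFGS iterations; ``tol`` is its convergence tolerance
    (the early-stopping criterion).  ``seed`` makes the whole procedure
    reproducible bit-for-bit.
    """

    restarts: int = 20
    alpha_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    hidden_layers: tuple[int, ...] = HIDDEN_LAYERS

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not self.alpha_grid:
            raise ValueError("alpha_grid must be non-empty")

    def restart_seed(self, r: int) -> int:
        return int((self.seed + 1009 * (r + 1)) % (2**31 - 1))


@dataclass(frozen=True)
class RestartRecord:
    """Validation diagnostics of one training restart."""

    index: int
    seed: int
    alpha: float
    val_accuracy: float
    val_log_loss: float
    n_iter: int


@dataclass
class MlpModel:
    """A trained network plus its input-normalization constants.

    ``weights[l]`` has shape (n_in, n_out) for layer ``l`` and
    ``biases[l]`` shape (n_out,); hidden activations are tanh, the output
    is a softmax over ``classes`` (canonical sub-technique order).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    classes: tuple[SubTechnique, ...]
    seed: int = 0
    alpha: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float).reshape(-1) for b in self.biases]
        self.feature_mean = np.asarray(self.feature_mean, dtype=float).reshape(-1)
        self.feature_std = np.asarray(self.feature_std, dtype=float).reshape(-1)
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases length mismatch")
        for w, b in zip(self.weights, self.biases):
            if w.shape[1] != b.shape[0]:
                raise ValueError("inconsistent layer shapes")
        for wa, wb in zip(self.weights[:-1], self.weights[1:]):
            if wa.shape[1] != wb.shape[0]:
                raise ValueError("inconsistent consecutive layer shapes")
        if self.weights[-1].shape[1] != len(self.classes):
            raise ValueError("output layer width must equal number of classes")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    # -- forward pass -------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for an (n, 94) matrix of raw features."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[1]} != expected {self.n_features}"
            )
        h = (X - self.feature_mean) / self.feature_std
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, feature) -> tuple[SubTechnique, np.ndarray]:
        """Classify a single 94-element feature vector.

        Returns the argmax class (ties broken by canonical class order,
        which is the probability-vector order) and the probabilities.
        """
        values = getattr(feature, "values", feature)
        probs = self.predict_proba(np.asarray(values).reshape(1, -1))[0]
        return self.classes[int(np.argmax(probs))], probs

    def predict_labels(self, X: np.ndarray) -> list[SubTechnique]:
        probs = self.predict_proba(X)
        return [self.classes[i] for i in np.argmax(probs, axis=1)]

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": _MODEL_FORMAT,
            "version": _MODEL_VERSION,
            "layer_sizes": list(self.layer_sizes),
            "classes": [c.value for c in self.classes],
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "seed": self.seed,
            "alpha": self.alpha,
            "metadata": self.metadata,
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MlpModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != _MODEL_FORMAT:
            raise ValueError(f"{path}: not a {_MODEL_FORMAT} model file")
        return cls(
            weights=[np.asarray(w) for w in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
            feature_mean=np.asarray(payload["feature_mean"]),
            feature_std=np.asarray(payload["feature_std"]),
            classes=tuple(SubTechnique.parse(c) for c in payload["classes"]),
            seed=int(payload.get("seed", 0)),
            alpha=float(payload.get("alpha", 0.0)),
            metadata=payload.get("metadata", {}),
        )


def _validate_training_inputs(y_train, y_val) -> list[SubTechnique]:
    if SubTechnique.EXC in y_train or SubTechnique.EXC in y_val:
        raise ValueError("EXC must never appear in training or validation targets")
    present = [c for c in CLASSES if c in set(y_train)]
    if len(present) < 2:
        raise ValueError("training set must cover at least 2 classes")
    if len(y_val) == 0:
        raise ValueError("validation set must not be empty")
    return present


def _to_canonical_weights(clf: MLPClassifier, classes: list[SubTechnique]):
    """Extract (weights, biases) with a softmax output over ``classes``.

    For binary problems sklearn uses a single logistic output; it is
    converted to the equivalent two-column softmax layer so the in-package
    forward pass is uniform across class counts.
    """
    weights = [np.asarray(w) for w in clf.coefs_]
    biases = [np.asarray(b) for b in clf.intercepts_]
    if len(classes) == 2 and weights[-1].shape[1] == 1:
        w, b = weights[-1], biases[-1]
        weights[-1] = np.hstack([np.zeros_like(w), w])
        biases[-1] = np.concatenate([[0.0], b])
    return weights, biases


def train(
    X_train: np.ndarray,
    y_train: Sequence[SubTechnique],
    X_val: np.ndarray,
    y_val: Sequence[SubTechnique],
    config: TrainConfig | None = None,
) -> tuple[MlpModel, list[RestartRecord]]:
    """Train the classifier with random restarts and validation selection.

    Returns the selected model (carrying normalization constants computed
    on the training set only) and the per-restart records, in restart
    order.  With a fixed config the result is reproducible bit-for-bit.
    """
    config = config or TrainConfig()
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = list(y_train)
    y_val = list(y_val)
    classes = _validate_training_inputs(y_train, y_val)
    class_index = {c: i for i, c in enumerate(classes)}
    yt = np.asarray([class_index[c] for c in y_train])
    unseen = set(y_val) - set(classes)
    if unseen:
        raise ValueError(f"validation labels {sorted(str(c) for c in unseen)} unseen in training")
    yv = np.asarray([class_index[c] for c in y_val])

    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Zt = (X_train - mean) / std
    Zv = (X_val - mean) / std

    records: list[RestartRecord] = []
    best: tuple | None = None  # (-acc, logloss, index)
    best_clf = None
    for r in range(config.restarts):
        alpha = config.alpha_grid[r % len(config.alpha_grid)]
        seed = config.restart_seed(r)
        clf = MLPClassifier(
            hidden_layer_sizes=config.hidden_layers,
            activation="tanh",
            solver="lbfgs",
            alpha=alpha,
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=seed,
        )
        clf.fit(Zt, yt)
        proba = clf.predict_proba(Zv)
        pred = np.argmax(proba, axis=1)
        acc = float(np.mean(pred == yv))
        eps = 1e-12
        ll = float(-np.mean(np.log(np.clip(proba[np.arange(len(yv)), yv], eps, 1.0))))
        records.append(RestartRecord(r, seed, alpha, 100.0 * acc, ll, int(clf.n_iter_)))
        key = (-acc, ll, r)
        if best is None or key < best:
            best = key
            best_clf = clf

    weights, biases = _to_canonical_weights(best_clf, classes)
    selected = records[best[2]]
    model = MlpModel(
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_std=std,
        classes=tuple(classes),
        seed=selected.seed,
        alpha=selected.alpha,
        metadata={
            "restarts": config.restarts,
            "selected_restart": selected.index,
            "val_accuracy_pct": selected.val_accuracy,
            "val_log_loss": selected.val_log_loss,
            "n_train": int(X_train.shape[0]),
            "n_val": int(X_val.shape[0]),
        },
    )
    return model, records


def predict(model: MlpModel, feature) -> tuple[SubTechnique, np.ndarray]:
    """Functional alias of :meth:`MlpModel.predict`."""
    return model.predict(feature)


# ---------------------------------------------------------------------------
# Full-session pipeline
# ---------------------------------------------------------------------------

def classify_session(
    model: MlpModel,
    arm_gyro: ImuSeries | None,
    chest_accel: ImuSeries | None,
    detection_filter: _pre.FilterSpec = _pre.DETECTION_FILTER,
    feature_filter: _pre.FilterSpec = _pre.FEATURE_FILTER,
) -> list[tuple[Cycle, SubTechnique]]:
    """Run the full pipeline on a two-sensor session.

    calibrate arm gyro -> heavy filter -> peak-based cycle detection ->
    exclusion marking -> light filter of the chest accelerometer ->
    per-cycle 94-feature extraction -> network prediction.  Partial
    leading/trailing segments and cycles overlapping missing-data spans
    are labeled EXC, not classified.
    """
    if arm_gyro is None:
        raise ValueError("missing stream: arm gyroscope")
    if chest_accel is None:
        raise ValueError("missing stream: chest accelerometer")
    if arm_gyro.modality != "gyroscope" or not arm_gyro.placement.startswith("arm"):
        raise ValueError("arm stream must be an arm-mounted gyroscope")
    if chest_accel.modality != "accelerometer" or chest_accel.placement != "chest":
        raise ValueError("chest stream must be a chest-mounted accelerometer")

    min_len = int(4 * detection_filter.sigma_samples(arm_gyro.sample_rate_hz)) + 2
    if arm_gyro.n < min_len or chest_accel.n < min_len:
        return []

    calibrated, _ = _pre.calibrate_arm(arm_gyro, detection_filter)
    gy = _pre.gaussian_filter(calibrated, detection_filter).y
    detected = _cycles.detect_cycles(gy, arm_gyro.sample_rate_hz)
    detected = _cycles.mark_excluded(
        detected, arm_gyro.missing_spans, chest_accel.missing_spans
    )
    chest_f = _pre.gaussian_filter(chest_accel, feature_filter)

    out: list[tuple[Cycle, SubTechnique]] = []
    for c in detected:
        if c.excluded or c.partial or c.end > chest_f.n:
            out.append((c, SubTechnique.EXC))
            continue
        feature = _features.extract_features(chest_f, c)
        label, _ = model.predict(feature)
        out.append((c, label))
    return out


# ---------------------------------------------------------------------------
# Model/Results surface
# ---------------------------------------------------------------------------

class SubTechniqueClassifier:
    """The classifier as a model object bound to its data.

    Construct from design matrices (or featurized labeled cycles via
    :meth:`from_labeled_cycles`), then call :meth:`fit`; the returned
    :class:`ClassifierFit` carries the selected network, all restart
    diagnostics and the validation confusion matrix.
    """

    def __init__(
        self,
        X_train: np.ndarray,
        y_train: Sequence[SubTechnique],
        X_val: np.ndarray,
        y_val: Sequence[SubTechnique],
    ) -> None:
        self.X_train = np.asarray(X_train, dtype=float)
        self.y_train = list(y_train)
        self.X_val = np.asarray(X_val, dtype=float)
        self.y_val = list(y_val)
        _validate_training_inputs(self.y_train, self.y_val)

    @classmethod
    def from_labeled_cycles(cls, train_set, val_set) -> "SubTechniqueClassifier":
        Xt, yt = _features.feature_matrix(train_set)
        Xv, yv = _features.feature_matrix(val_set)
        return cls(Xt, yt, Xv, yv)

    def fit(self, config: TrainConfig | None = None) -> "ClassifierFit":
        config = config or TrainConfig()
        model, records = train(self.X_train, self.y_train, self.X_val, self.y_val, config)
        train_pred = model.predict_labels(self.X_train)
        val_pred = model.predict_labels(self.X_val)
        train_acc = 100.0 * float(np.mean([p is t for p, t in zip(train_pred, self.y_train)]))
        val_cm = build_confusion(zip(self.y_val, val_pred), model.classes)
        return ClassifierFit(self, config, model, records, train_acc, val_cm)


@dataclass
class ClassifierFit:
    """Results of fitting :class:`SubTechniqueClassifier`."""

    model_spec: SubTechniqueClassifier
    config: TrainConfig
    model: MlpModel
    restarts: list[RestartRecord]
    train_accuracy_pct: float
    val_confusion: ConfusionMatrix

    @property
    def val_accuracy_pct(self) -> float:
        return float(self.val_confusion.accuracy())

    @property
    def selected_restart(self) -> RestartRecord:
        return self.restarts[int(self.model.metadata["selected_restart"])]

    def summary(self) -> str:
        lines = [
            "Sub-technique MLP classifier",
            "=" * 60,
            f"architecture        : {' -> '.join(map(str, self.model.layer_sizes))}"
            " (tanh hidden, softmax output)",
            f"training cycles     : {len(self.model_spec.y_train)}",
            f"validation cycles   : {len(self.model_spec.y_val)}",
            f"restarts            : {self.config.restarts}"
            f" (selected #{self.selected_restart.index},"
            f" alpha={self.selected_restart.alpha:g})",
            f"training accuracy   : {self.train_accuracy_pct:.1f}%",
            f"validation accuracy : {self.val_accuracy_pct:.1f}%",
            "",
            "restart  alpha     val_acc%  val_logloss  iters",
        ]
        for r in self.restarts:
            mark = " *" if r.index == self.selected_restart.index else ""
            lines.append(
                f"{r.index:>7d}  {r.alpha:<8g}  {r.val_accuracy:>7.2f}"
                f"  {r.val_log_loss:>11.4f}  {r.n_iter:>5d}{mark}"
            )
        lines += ["", "Validation confusion matrix:", self.val_confusion.render()]
        return "\n".join(lines)
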