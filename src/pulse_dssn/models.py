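"""Base learners and meta-learner for pulse-type classification.

Three base learners and one meta-learner, with the reference settings:

* **RBF-SVM** (one for the 23 time-domain features, one for the 256
  wavelet-band energies): C = 2.0, gamma = 3.0.  Inputs are min-max scaled
  to [0, 1] inside the pipeline (fit on training data), under which this
  gamma is a sensible kernel width.  Class probabilities come from
  scikit-learn's pairwise-coupling (Platt) calibration, because stacking
  consumes soft outputs.  An optional grid search reproduces the published
  search protocol (C in 1..50 step 1, gamma in 1..50 step 0.5).
* **1D-DCNN** on the length-800 cycle: three conv layers (5x11, 25x9,
  100x10), each followed by ReLU and max-pooling of size 2, dropout 0.5
  before a 7-unit softmax dense layer; batch size 8.
* **FCNN meta-learner** on the 21 concatenated base-learner probabilities:
  dense 1024-1024-512-7 (ReLU / softmax); batch size 32.

All neural learners train with cross-entropy, SGD (lr 0.001, momentum 0.9,
weight decay 1e-4), at most 1000 epochs, and early stopping with patience
10 on validation loss (best-loss weights restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .core import FIXED_LENGTH, N_CLASSES
from .nn import Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU, TrainLog

__all__ = [
    "SvmConfig",
    "DcnnConfig",
    "FcnnConfig",
    "SvmLearner",
    "NetLearner",
    "fit_svm",
    "fit_dcnn",
    "fit_fcnn",
    "predict_proba",
]

ALL_CLASSES = tuple(range(1, N_CLASSES + 1))


@dataclass(frozen=True)
class SvmConfig:
    C: float = 2.0
    gamma: float = 3.0
    kernel: str = "rbf"
    grid_C: tuple[float, float, float] = (1.0, 50.0, 1.0)  # lo, hi, step
    grid_gamma: tuple[float, float, float] = (1.0, 50.0, 0.5)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    def grid_candidates(self) -> list[tuple[float, float]]:
        c_lo, c_hi, c_st = self.grid_C
        g_lo, g_hi, g_st = self.grid_gamma
        cs = np.arange(c_lo, c_hi + 1e-9, c_st)
        gs = np.arange(g_lo, g_hi + 1e-9, g_st)
        return [(float(c), float(g)) for c in cs for g in gs]


@dataclass(frozen=True)
class DcnnConfig:
    conv_layers: tuple[tuple[int, int], ...] = ((5, 11), (25, 9), (100, 10))
    dense_units: int = N_CLASSES
    input_length: int = FIXED_LENGTH
    batch_size: int = 8
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    dropout: float = 0.5
    max_epochs: int = 1000
    patience: int = 10


@dataclass(frozen=True)
class FcnnConfig:
    dense_layers: tuple[int, ...] = (1024, 1024, 512, N_CLASSES)
    batch_size: int = 32
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    dropout: float = 0.0
    max_epochs: int = 1000
    patience: int = 10


class _Learner:
    """Common surface: fitted model exposing 7-class probabilities."""

    classes_: tuple[int, ...] = ALL_CLASSES

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.array([self.classes_[i] for i in proba.argmax(axis=1)])


class SvmLearner(_Learner):
    def __init__(self, pipeline: Pipeline, config: SvmConfig):
        self.pipeline = pipeline
        self.config = config
        self._fitted_classes = tuple(int(c) for c in pipeline[-1].classes_)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty((0, N_CLASSES))
        raw = self.pipeline.predict_proba(X)
        out = np.zeros((X.shape[0], N_CLASSES))
        for j, c in enumerate(self._fitted_classes):
            out[:, c - 1] = raw[:, j]
        return out


class NetLearner(_Learner):
    def __init__(self, net: Network, log: TrainLog, input_shape: tuple[int, ...]):
        self.net = net
        self.log = log
        self.input_shape = input_shape

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.shape[0] == 0:
            return np.empty((0, N_CLASSES))
        return self.net.predict_proba(X.reshape((X.shape[0],) + self.input_shape))


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not set(np.unique(y)) <= set(ALL_CLASSES):
        raise ValueError(f"labels must be class codes 1-{N_CLASSES}")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    return y


def fit_svm(
    features: np.ndarray,
    labels: np.ndarray,
    config: SvmConfig = SvmConfig(),
    grid_search: bool = False,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> SvmLearner:
    """Fit an RBF-SVM with probability outputs over the 7 classes.

    With ``grid_search`` the (C, gamma) pair maximising validation
    macro-accuracy (mean per-class recall) over the published grid is
    selected; a validation set is then required.
    """
    X = np.asarray(features, dtype=float)
    y = _check_labels(labels)

    def build(c: float, g: float) -> Pipeline:
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                ("svc", SVC(C=c, gamma=g, kernel=config.kernel, probability=True,
                            random_state=seed)),
            ]
        )

    import warnings

    def fit_quiet(pipe: Pipeline) -> Pipeline:
        with warnings.catch_warnings():
            # SVC(probability=True) is the pairwise-coupling path we want;
            # sklearn 1.9 nags about its future replacement
            warnings.simplefilter("ignore", FutureWarning)
            return pipe.fit(X, y)

    if grid_search:
        if validation is None:
            raise ValueError("grid_search requires a validation set")
        Xv, yv = validation
        best, best_score = None, -np.inf
        for c, g in config.grid_candidates():
            pipe = fit_quiet(build(c, g))
            pred = pipe.predict(Xv)
            score = _macro_accuracy(yv, pred)
            if score > best_score:
                best, best_score = pipe, score
        assert best is not None
        return SvmLearner(best, config)
    return SvmLearner(fit_quiet(build(config.C, config.gamma)), config)


def _macro_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present in y_true."""
    classes = np.unique(y_true)
    return float(np.mean([np.mean(y_pred[y_true == c] == c) for c in classes]))


def build_dcnn(config: DcnnConfig, rng: np.random.Generator) -> Network:
    """Assemble the conv stack and infer the flattened dense input size."""
    layers: list = []
    length = config.input_length
    channels = 1
    for filters, kernel in config.conv_layers:
        layers.append(Conv1D(channels, filters, kernel, rng))
        layers.append(ReLU())
        layers.append(MaxPool1D())
        length = (length - kernel + 1) // 2
        channels = filters
    if length < 1:
        raise ValueError("input too short for the configured conv stack")
    layers.append(Dropout(config.dropout, rng))
    layers.append(Flatten())
    layers.append(Dense(channels * length, config.dense_units, rng))
    return Network(layers)


def fit_dcnn(
    cycles: np.ndarray,
    labels: np.ndarray,
    validation: tuple[np.ndarray, np.ndarray],
    config: DcnnConfig = DcnnConfig(),
    seed: int = 0,
) -> NetLearner:
    """Train the 1-D CNN on length-800 cycles (rows of ``cycles``)."""
    X = np.asarray(cycles, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != config.input_length:
        raise ValueError(
            f"cycles must be (n, {config.input_length}), got {X.shape}"
        )
    y = _check_labels(labels)
    Xv, yv = validation
    Xv = np.asarray(Xv, dtype=np.float32)
    if Xv.ndim != 2 or Xv.shape[1] != config.input_length:
        raise ValueError(f"validation cycles must be (n, {config.input_length})")
    rng = np.random.default_rng(seed)
    net = build_dcnn(config, rng)
    log = net.fit(
        X.reshape(-1, 1, config.input_length),
        y - 1,
        Xv.reshape(-1, 1, config.input_length),
        np.asarray(yv) - 1,
        rng,
        batch_size=config.batch_size,
        lr=config.lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
        max_epochs=config.max_epochs,
        patience=config.patience,
    )
    return NetLearner(net, log, input_shape=(1, config.input_length))


def fit_fcnn(
    meta_features: np.ndarray,
    labels: np.ndarray,
    validation: tuple[np.ndarray, np.ndarray],
    config: FcnnConfig = FcnnConfig(),
    seed: int = 0,
) -> NetLearner:
    """Train the fully connected meta-learner on stacked base outputs."""
    X = np.asarray(meta_features, dtype=np.float32)
    if X.ndim != 2:
        raise ValueError("meta_features must be 2-D")
    y = _check_labels(labels)
    Xv, yv = validation
    rng = np.random.default_rng(seed)
    layers: list = []
    dim = X.shape[1]
    for i, units in enumerate(config.dense_layers):
        layers.append(Dense(dim, units, rng))
        if i < len(config.dense_layers) - 1:
            layers.append(ReLU())
            if config.dropout > 0:
                layers.append(Dropout(config.dropout, rng))
        dim = units
    net = Network(layers)
    log = net.fit(
        X,
        y - 1,
        np.asarray(Xv, dtype=np.float32),
        np.asarray(yv) - 1,
        rng,
        batch_size=config.batch_size,
        lr=config.lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
        max_epochs=config.max_epochs,
        patience=config.patience,
    )
    return NetLearner(net, log, input_shape=(X.shape[1],))


def predict_proba(model: _Learner, inputs: np.ndarray) -> np.ndarray:
    """Per-sample 7-class probability rows (argmax = predicted class)."""
    if not isinstance(model, _Learner):
        raise TypeError(f"not a fitted learner: {type(model)}")
    return model.predict_proba(np.asarray(inputs))
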