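"""Conventional classifiers on raw instantaneous sEMG vectors.

Five baselines share the :class:`~semgimg.voting.FramePredictions` contract
with the ConvNet: an MLP (single hidden layer of 1024 ReLU units, trained
with the same SGD recipe as the ConvNet) and scikit-learn KNN, SVM, Random
Forest and LDA with pinned default hyper-parameters.  Training vectors may
be decimated by taking every k-th frame for computational ease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .convnet.layers import Dense, ReLU, softmax, softmax_cross_entropy
from .convnet.model import TrainSpec, lr_for_epoch

__all__ = [
    "BaselineSpec",
    "BASELINE_DEFAULTS",
    "fit_baseline",
    "predict_baseline",
    "decimate_training_set",
    "MlpClassifier",
]

# Hyper-parameters pinned here rather than inherited from the installed
# scikit-learn version, so results survive upstream default drift.
BASELINE_DEFAULTS: dict[str, dict[str, Any]] = {
    "knn": {"n_neighbors": 5, "weights": "uniform", "algorithm": "auto", "p": 2},
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "rf": {"n_estimators": 100, "criterion": "gini", "max_features": "sqrt"},
    "lda": {"solver": "svd", "shrinkage": None},
    "mlp": {"hidden_units": 1024},
}

KINDS = ("mlp", "knn", "svm", "rf", "lda")


@dataclass(frozen=True)
class BaselineSpec:
    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    train_downsample_factor: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; known: {KINDS}")
        if self.train_downsample_factor < 1:
            raise ValueError("train_downsample_factor must be at least 1")

    def resolved_hyperparameters(self) -> dict[str, Any]:
        params = dict(BASELINE_DEFAULTS[self.kind])
        params.update(self.hyperparameters)
        return params


class MlpClassifier:
    """Single-hidden-layer MLP trained with the ConvNet's SGD recipe."""

    def __init__(self, n_in: int, n_classes: int, hidden_units: int = 1024, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.layers = [Dense(n_in, hidden_units, rng), ReLU(), Dense(hidden_units, n_classes, rng)]

    def fit(self, x: np.ndarray, y: np.ndarray, train_spec: TrainSpec) -> list[float]:
        rng = np.random.default_rng([train_spec.seed, 13])
        n = x.shape[0]
        trace = []
        for epoch in range(1, train_spec.epochs + 1):
            lr = lr_for_epoch(train_spec, epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, train_spec.batch_size):
                idx = order[start : start + train_spec.batch_size]
                h = x[idx]
                for layer in self.layers:
                    h = layer.forward(h, train=True)
                loss, dy = softmax_cross_entropy(h, y[idx])
                for layer in reversed(self.layers):
                    dy = layer.backward(dy)
                for layer in self.layers:
                    for name, p in layer.params.items():
                        g = layer.grads[name]
                        if name in layer.decayed and train_spec.weight_decay:
                            g = g + train_spec.weight_decay * p
                        p -= lr * g
                losses.append(loss)
            trace.append(float(np.mean(losses)))
        return trace

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            h = layer.forward(h, train=False)
        return softmax(h)


def decimate_training_set(
    vectors: np.ndarray, labels: np.ndarray, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Take every ``factor``-th frame (stride sampling, deterministic)."""
    return vectors[::factor], labels[::factor]


def _make_sklearn(spec: BaselineSpec):
    params = spec.resolved_hyperparameters()
    if spec.kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(**params)
    if spec.kind == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=spec.seed, **params)
    if spec.kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.kind == "lda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        return LinearDiscriminantAnalysis(**params)
    raise AssertionError(spec.kind)


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    model: Any
    classes: np.ndarray
    n_features: int


def fit_baseline(
    spec: BaselineSpec,
    vectors: np.ndarray,
    labels: np.ndarray,
    train_spec: TrainSpec | None = None,
) -> FittedBaseline:
    """Fit one baseline on (possibly decimated) instantaneous vectors."""
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if vectors.ndim != 2 or vectors.shape[0] != labels.shape[0]:
        raise ValueError("vectors must be (n_frames, n_channels) aligned with labels")
    vectors, labels = decimate_training_set(vectors, labels, spec.train_downsample_factor)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training set must contain at least two classes")
    if spec.kind == "mlp":
        params = spec.resolved_hyperparameters()
        model = MlpClassifier(
            vectors.shape[1],
            int(classes.max()) + 1,
            hidden_units=params["hidden_units"],
            seed=spec.seed,
        )
        model.fit(vectors, labels, train_spec or TrainSpec(seed=spec.seed))
        classes = np.arange(model.n_classes)
    else:
        model = _make_sklearn(spec)
        model.fit(vectors, labels)
        classes = model.classes_
    return FittedBaseline(spec, model, np.asarray(classes), vectors.shape[1])


def predict_baseline(fitted: FittedBaseline, vectors: np.ndarray) -> np.ndarray:
    """Per-frame probability vectors over ``max(classes)+1`` classes.

    Models without calibrated probabilities (default SVC, LDA-free kinds)
    fall back to one-hot vectors of their hard decisions.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[1] != fitted.n_features:
        raise ValueError(
            f"vectors must be (n, {fitted.n_features}), got {vectors.shape}"
        )
    n_classes = int(fitted.classes.max()) + 1
    probs = np.zeros((vectors.shape[0], n_classes))
    model = fitted.model
    if hasattr(model, "predict_proba"):
        p = model.predict_proba(vectors)
        if isinstance(model, MlpClassifier):
            probs = p
        else:
            probs[:, fitted.classes] = p
    else:
        hard = model.predict(vectors)
        probs[np.arange(len(hard)), hard] = 1.0
    return probs
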