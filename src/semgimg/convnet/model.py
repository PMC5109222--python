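"""Small convolutional network for per-frame sEMG-image classification.

Architecture (hidden layers numbered 1-8 including the output):
two 3x3/stride-1 convolutions with 64 filters, two locally connected
layers of 64 unshared 1x1 filters, three dense layers of 512, 512 and 128
units, and a G-way dense output with softmax.  ReLU follows each hidden
layer, batch normalization sits after the input and before every
non-linearity, and dropout (p = 0.5) acts on hidden layers 4-6.

Training uses plain SGD with batch size 1000, 28 epochs, weight decay 1e-4
and a 0.1 learning rate divided by 10 after epochs 16 and 24 (1-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (
    BatchNorm,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    Layer,
    LocallyConnected1x1,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = ["ConvNetSpec", "TrainSpec", "ConvNet", "build", "pretrain_union", "lr_for_epoch"]


@dataclass(frozen=True)
class ConvNetSpec:
    """Architecture parameterization; defaults follow the reference recipe."""

    input_shape: tuple[int, int, int]  # (rows, cols, channels)
    n_classes: int
    n_conv_layers: int = 2
    n_filters: int = 64
    kernel: int = 3
    n_local_layers: int = 2
    dense_units: tuple[int, ...] = (512, 512, 128)
    dropout_p: float = 0.5
    #: 1-based indices of hidden layers followed by dropout
    dropout_layers: tuple[int, ...] = (4, 5, 6)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        rows, cols, ch = self.input_shape
        if rows < 1 or cols < 1 or ch < 1:
            raise ValueError("invalid input shape")

    @property
    def n_hidden_layers(self) -> int:
        return self.n_conv_layers + self.n_local_layers + len(self.dense_units)


@dataclass(frozen=True)
class TrainSpec:
    """SGD recipe; epoch indexing is 1-based for the learning-rate drops."""

    batch_size: int = 1000
    epochs: int = 28
    lr: float = 0.1
    lr_drop_epochs: tuple[int, ...] = (16, 24)
    lr_drop_factor: float = 10.0
    weight_decay: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")


def lr_for_epoch(spec: TrainSpec, epoch: int) -> float:
    """Learning rate during 1-based ``epoch`` (drops apply *after* each listed epoch)."""
    drops = sum(1 for d in spec.lr_drop_epochs if epoch > d)
    return spec.lr / spec.lr_drop_factor**drops


class ConvNet:
    """Feed-forward network assembled from seeded NumPy layers."""

    def __init__(self, spec: ConvNetSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng([seed, 7])
        rows, cols, ch = spec.input_shape
        layers: list[Layer] = [BatchNorm(ch)]
        hidden = 0
        c_in = ch
        for _ in range(spec.n_conv_layers):
            hidden += 1
            layers += [Conv2d(c_in, spec.n_filters, spec.kernel, rng), BatchNorm(spec.n_filters), ReLU()]
            if hidden in spec.dropout_layers:
                layers.append(Dropout(spec.dropout_p, self._dropout_rng))
            c_in = spec.n_filters
        for _ in range(spec.n_local_layers):
            hidden += 1
            layers += [
                LocallyConnected1x1(c_in, spec.n_filters, rows, cols, rng),
                BatchNorm(spec.n_filters),
                ReLU(),
            ]
            if hidden in spec.dropout_layers:
                layers.append(Dropout(spec.dropout_p, self._dropout_rng))
            c_in = spec.n_filters
        layers.append(Flatten())
        n_in = c_in * rows * cols
        for units in spec.dense_units:
            hidden += 1
            layers += [Dense(n_in, units, rng), BatchNorm(units), ReLU()]
            if hidden in spec.dropout_layers:
                layers.append(Dropout(spec.dropout_p, self._dropout_rng))
            n_in = units
        layers.append(Dense(n_in, spec.n_classes, rng))
        self.layers = layers

    # ------------------------------------------------------------------ core

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        from .layers import DTYPE

        images = np.asarray(images, dtype=DTYPE)
        rows, cols, ch = self.spec.input_shape
        if images.ndim == 3:
            images = images[:, None, :, :]
        if images.ndim != 4 or images.shape[1:] != (ch, rows, cols):
            raise ValueError(
                f"expected images of shape (n, {ch}, {rows}, {cols}), got {images.shape}"
            )
        return images

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_images(images)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, images: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Per-frame class probabilities (inference mode, deterministic)."""
        images = self._check_images(images)
        out = [
            softmax(self.logits(images[i : i + batch_size]).astype(np.float64))
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        train_spec: TrainSpec | None = None,
        verbose: bool = False,
    ) -> list[float]:
        """SGD training; returns the per-epoch mean loss trace."""
        train_spec = train_spec or TrainSpec()
        images = self._check_images(images)
        labels = np.asarray(labels, dtype=np.intp)
        if labels.shape != (images.shape[0],):
            raise ValueError("labels must align with images")
        if labels.size == 0:
            raise ValueError("empty training set")
        if labels.min() < 0 or labels.max() >= self.spec.n_classes:
            raise ValueError(
                f"labels must lie in [0, {self.spec.n_classes}); got range "
                f"[{labels.min()}, {labels.max()}]"
            )
        rng = np.random.default_rng([train_spec.seed, 11])
        n = images.shape[0]
        trace: list[float] = []
        for epoch in range(1, train_spec.epochs + 1):
            lr = lr_for_epoch(train_spec, epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, train_spec.batch_size):
                idx = order[start : start + train_spec.batch_size]
                loss, dlogits = softmax_cross_entropy(
                    self.logits(images[idx], train=True), labels[idx]
                )
                self._backward(dlogits)
                self._sgd_step(lr, train_spec.weight_decay)
                losses.append(loss)
            trace.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch:3d}  lr {lr:.4g}  loss {trace[-1]:.4f}")
        # Exponential running averages lag the final weights on short runs;
        # one exact pass over the training set fixes the inference statistics.
        self.recalibrate_bn(images)
        return trace

    def _backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def _sgd_step(self, lr: float, weight_decay: float) -> None:
        for layer in self.layers:
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                if name in layer.decayed and weight_decay:
                    g = g + weight_decay * p
                p -= lr * g

    # ------------------------------------------------- batch-norm recalibration

    def recalibrate_bn(self, images: np.ndarray, batch_size: int = 2048) -> "ConvNet":
        """Recompute all batch-norm running statistics from unlabeled images.

        Only the running mean/variance of each batch-norm layer change;
        every learned weight is untouched.
        """
        images = self._check_images(images)
        if images.shape[0] < 2:
            raise ValueError("batch-norm recalibration requires at least two images")
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            bn.begin_calibration()
        try:
            for i in range(0, len(images), batch_size):
                self.logits(images[i : i + batch_size], train=False)
        finally:
            for bn in bns:
                bn.end_calibration()
        return self

    # ------------------------------------------------------------ persistence

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"layer{i:02d}/{name}"] = p
            if isinstance(layer, BatchNorm):
                out[f"layer{i:02d}/running_mean"] = layer.running_mean
                out[f"layer{i:02d}/running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i:02d}/{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(state[f"layer{i:02d}/running_mean"])
                layer.running_var = np.array(state[f"layer{i:02d}/running_var"])

    def save(self, path) -> None:
        """Checkpoint spec + weights + batch-norm statistics to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["spec"] = json.dumps(asdict(self.spec))
            f.attrs["seed"] = self.seed
            for key, arr in self.state_arrays().items():
                f.create_dataset(key, data=arr)

    @classmethod
    def load(cls, path) -> "ConvNet":
        import h5py

        with h5py.File(path, "r") as f:
            raw = json.loads(f.attrs["spec"])
            raw["input_shape"] = tuple(raw["input_shape"])
            raw["dense_units"] = tuple(raw["dense_units"])
            raw["dropout_layers"] = tuple(raw["dropout_layers"])
            model = cls(ConvNetSpec(**raw), seed=int(f.attrs["seed"]))
            state = {k: np.array(f[k]) for k in _h5_keys(f)}
        model.load_state_arrays(state)
        return model

    def copy(self) -> "ConvNet":
        clone = ConvNet(self.spec, seed=self.seed)
        clone.load_state_arrays({k: v.copy() for k, v in self.state_arrays().items()})
        return clone


def _h5_keys(f) -> list[str]:
    keys: list[str] = []
    f.visit(lambda name: keys.append(name) if _is_dataset(f, name) else None)
    return keys


def _is_dataset(f, name: str) -> bool:
    import h5py

    return isinstance(f[name], h5py.Dataset)


def build(spec: ConvNetSpec, seed: int = 0) -> ConvNet:
    """Construct a freshly He-initialized network."""
    return ConvNet(spec, seed=seed)


def pretrain_union(
    model: ConvNet,
    training_sets: list[tuple[np.ndarray, np.ndarray]],
    train_spec: TrainSpec | None = None,
) -> ConvNet:
    """Initialize by training on the union of all subjects' training sets.

    The returned model's weights serve as the starting point for
    per-subject fine-tuning; with a single subject this is ordinary
    training on that subject.
    """
    if not training_sets:
        raise ValueError("pre-training requires at least one training set")
    images = np.concatenate([np.asarray(x) for x, _ in training_sets], axis=0)
    labels = np.concatenate([np.asarray(y) for _, y in training_sets], axis=0)
    model.fit(images, labels, train_spec)
    return model
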