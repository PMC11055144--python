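"""The action-image classification model and its training loop.

The architecture is four convolution blocks — kernel sizes 5x5, 3x3,
3x3, 3x3 with 16, 32, 64, 128 output channels, each block being
convolution (stride 1, valid padding, bias) -> ReLU -> 2x2 max pool
with stride 2 — followed by flatten -> dense(128) -> ReLU ->
dense(n_classes) -> softmax.  Training uses Adam on softmax
cross-entropy with either stratified 5-fold cross-validation or a
stratified 70/30 holdout split; every stochastic step is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigurationError, ValidationError
from .nn import (
    Adam,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)

SPLITS = ("five_fold_cv", "holdout_70_30")


@dataclass(frozen=True)
class ModelSpec:
    """Geometry and width of the classification network."""

    input_shape: tuple[int, int, int] = (200, 138, 3)
    conv_channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel_sizes: tuple[int, ...] = (5, 3, 3, 3)
    hidden_units: int = 128
    n_classes: int = 16

    def __post_init__(self) -> None:
        if len(self.conv_channels) != len(self.kernel_sizes):
            raise ConfigurationError("conv_channels and kernel_sizes must align")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Output shape after each block, validating the geometry."""
        h, w, c = self.input_shape
        shapes: list[tuple[str, tuple[int, ...]]] = []
        for i, (k, ch) in enumerate(zip(self.kernel_sizes, self.conv_channels), 1):
            if h < k or w < k:
                raise ConfigurationError(
                    f"conv{i} input {h}x{w} is smaller than its {k}x{k} kernel"
                )
            h, w = h - k + 1, w - k + 1
            shapes.append((f"conv{i}", (h, w, ch)))
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ConfigurationError(f"pool{i} collapses the feature map")
            shapes.append((f"pool{i}", (h, w, ch)))
            c = ch
        flat = h * w * c
        shapes.append(("flatten", (flat,)))
        shapes.append(("fc1", (self.hidden_units,)))
        shapes.append(("fc2", (self.n_classes,)))
        return shapes


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    split: str = "five_fold_cv"
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.split not in SPLITS:
            raise ConfigurationError(f"split must be one of {SPLITS}")
        if self.n_folds < 2:
            raise ConfigurationError("need at least 2 folds")


# -- parameter accounting ----------------------------------------------

def conv_parameter_count(kh: int, kw: int, c_in: int, c_out: int) -> int:
    """Trainable parameters of one convolution layer: kh*kw*c_in*c_out + c_out."""
    return kh * kw * c_in * c_out + c_out


def dense_parameter_count(n_in: int, n_out: int) -> int:
    """Trainable parameters of one dense layer: n_in*n_out + n_out."""
    return n_in * n_out + n_out


def count_parameters(spec: ModelSpec) -> dict[str, int]:
    """Per-layer and total trainable parameter counts for a spec."""
    counts: dict[str, int] = {}
    c_in = spec.input_shape[2]
    for i, (k, c_out) in enumerate(zip(spec.kernel_sizes, spec.conv_channels), 1):
        counts[f"conv{i}"] = conv_parameter_count(k, k, c_in, c_out)
        c_in = c_out
    flat = dict(spec.layer_shapes())["flatten"][0]
    counts["fc1"] = dense_parameter_count(flat, spec.hidden_units)
    counts["fc2"] = dense_parameter_count(spec.hidden_units, spec.n_classes)
    counts["total"] = sum(counts.values())
    return counts


def build_model(spec: ModelSpec, seed: int) -> Sequential:
    """Instantiate the network with seeded He-normal initialization."""
    spec.layer_shapes()  # geometry validation
    rng = np.random.default_rng(seed)
    layers = []
    c_in = spec.input_shape[2]
    for k, c_out in zip(spec.kernel_sizes, spec.conv_channels):
        layers += [Conv2D(k, k, c_in, c_out, rng), ReLU(), MaxPool2()]
        c_in = c_out
    flat = dict(spec.layer_shapes())["flatten"][0]
    layers += [Flatten(), Dense(flat, spec.hidden_units, rng), ReLU(),
               Dense(spec.hidden_units, spec.n_classes, rng)]
    return Sequential(layers)


# -- training -----------------------------------------------------------

@dataclass
class FoldResult:
    model: Sequential
    history: dict[str, list[float]]
    train_indices: np.ndarray
    val_indices: np.ndarray
    val_probs: np.ndarray


@dataclass
class TrainResult:
    """Models and histories per fold plus pooled out-of-fold predictions."""

    folds: list[FoldResult]
    oof_probs: np.ndarray          # (N, n_classes); NaN rows never validated
    oof_labels: np.ndarray         # argmax of oof_probs, -1 where NaN

    @property
    def histories(self) -> list[dict[str, list[float]]]:
        return [f.history for f in self.folds]


def _as_batch_array(images) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValidationError(f"expected images of shape (N, H, W, 3), got {x.shape}")
    return x


def _fit(model, x_train, y_train, x_val, y_val, config, rng):
    opt = Adam(model.params, lr=config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_accuracy": []}
    n = len(x_train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(model.grads)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y_train[idx]).sum())
        history["loss"].append(sum(losses) / n)
        history["accuracy"].append(correct / n)
        val_pred = predict(model, x_val)[1] if len(x_val) else np.empty(0, int)
        history["val_accuracy"].append(
            float((val_pred == y_val).mean()) if len(x_val) else float("nan")
        )
    return history


def train(images, labels, spec: ModelSpec, config: TrainConfig) -> TrainResult:
    """Train under the configured split; fully reproducible given the seed.

    In ``five_fold_cv`` mode, stratified folds come from a seeded
    shuffle and one model is trained per fold; the pooled out-of-fold
    probabilities cover every example exactly once.  In
    ``holdout_70_30`` a single model is trained on a stratified 70%
    split and validated on the remaining 30%.
    """
    x = _as_batch_array(images)
    y = np.asarray(labels, dtype=int)
    if len(x) != len(y):
        raise ValidationError("images and labels length mismatch")
    if (x.shape[1], x.shape[2], x.shape[3]) != tuple(spec.input_shape):
        raise ValidationError(
            f"image geometry {x.shape[1:]} does not match spec {spec.input_shape}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")

    if config.split == "five_fold_cv":
        if counts.min() < config.n_folds:
            raise ValidationError(
                f"smallest class has {counts.min()} examples; needs >= {config.n_folds} folds"
            )
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        split_iter = list(splitter.split(x, y))
    else:
        tr, va = train_test_split(
            np.arange(len(y)), test_size=0.3, stratify=y, random_state=config.seed
        )
        split_iter = [(tr, va)]

    folds = []
    oof = np.full((len(y), spec.n_classes), np.nan)
    for fold_i, (tr, va) in enumerate(split_iter):
        model = build_model(spec, seed=config.seed + 1000 * (fold_i + 1))
        rng = np.random.default_rng(config.seed + 7919 * (fold_i + 1))
        history = _fit(model, x[tr], y[tr], x[va], y[va], config, rng)
        probs, _ = predict(model, x[va])
        oof[va] = probs
        folds.append(FoldResult(model, history, tr, va, probs))
    oof_labels = np.where(np.isnan(oof).any(axis=1), -1, np.nanargmax(
        np.nan_to_num(oof, nan=-np.inf), axis=1))
    return TrainResult(folds=folds, oof_probs=oof, oof_labels=oof_labels)


def predict(model: Sequential, images, batch_size: int = 64):
    """Class probabilities and argmax labels for a batch of images."""
    x = _as_batch_array(images)
    chunks = [
        softmax(model.forward(x[lo: lo + batch_size]).astype(np.float64))
        for lo in range(0, len(x), batch_size)
    ]
    probs = np.concatenate(chunks, axis=0) if chunks else np.empty((0, 0))
    return probs, probs.argmax(axis=1)


# -- serialization ------------------------------------------------------

def save_model(model: Sequential, spec: ModelSpec, path) -> None:
    """Weights as .npz next to a JSON architecture manifest."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{f"p{i}": p for i, p in enumerate(model.params)})
    manifest = {
        "input_shape": list(spec.input_shape),
        "conv_channels": list(spec.conv_channels),
        "kernel_sizes": list(spec.kernel_sizes),
        "hidden_units": spec.hidden_units,
        "n_classes": spec.n_classes,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_model(path) -> tuple[Sequential, ModelSpec]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(
        input_shape=tuple(manifest["input_shape"]),
        conv_channels=tuple(manifest["conv_channels"]),
        kernel_sizes=tuple(manifest["kernel_sizes"]),
        hidden_units=manifest["hidden_units"],
        n_classes=manifest["n_classes"],
    )
    model = build_model(spec, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights([data[f"p{i}"] for i in range(len(model.params))])
    return model, spec
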