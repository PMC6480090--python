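"""The fall-detection CNN architectures and their training recipe.

Three variants classify one accelerometer window as fall / not-fall:

* ``CNN-3B3Conv`` — Block 1: three conv1d layers (64 filters, kernel 4,
  ReLU, L2 0.01) + maxpool(3) + dropout(0.35); Block 2: the same with
  kernel 3; Block 3: dense 64 → 32 → 2.
* ``CNN-3Conv`` — Block 1 + Block 3 only.
* ``CNN-1Conv`` — Block 1 reduced to a single conv layer, + Block 3.

All convolutions are valid (no padding), stride 1.  The two output neurons
are read through a softmax; training minimizes the log-cosh between the
softmax output and the one-hot label with SGD (learning rate 0.0107,
momentum 0.999, Nesterov, per-update decay 1e-6) over 20 epochs — the
recipe is exposed as :class:`TrainConfig` so every number is overridable.

Label convention: fall = class index 1 = positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .signal_io import (LABEL_ADL, LABEL_FALL, LabeledDataset, Window)

VARIANTS = ("CNN-3B3Conv", "CNN-3Conv", "CNN-1Conv")

# architecture constants shared by all variants
N_FILTERS = 64
KERNEL_BLOCK1 = 4
KERNEL_BLOCK2 = 3
POOL_SIZE = 3
DROPOUT_RATE = 0.35
L2_COEFF = 0.01
DENSE_UNITS = (64, 32, 2)


class ArchitectureError(ValueError):
    """Raised when an input length cannot flow through a variant's layers."""


@dataclass(frozen=True)
class LayerSpec:
    """One declarative layer record; unused fields stay None."""

    kind: str  # conv1d | maxpool | dropout | flatten | dense
    filters: int | None = None
    kernel: int | None = None
    pool: int | None = None
    rate: float | None = None
    units: int | None = None
    activation: str | None = None
    l2: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


@dataclass(frozen=True)
class LayerStack:
    """A network variant as data: the layer sequence plus its input length."""

    variant: str
    input_length: int
    layers: tuple[LayerSpec, ...]

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "input_length": self.input_length,
            "layers": [l.to_dict() for l in self.layers],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LayerStack":
        d = json.loads(text)
        return cls(d["variant"], d["input_length"],
                   tuple(LayerSpec(**l) for l in d["layers"]))


def _conv_spec(kernel: int) -> LayerSpec:
    return LayerSpec(kind="conv1d", filters=N_FILTERS, kernel=kernel,
                     activation="relu", l2=L2_COEFF)


def _block(n_conv: int, kernel: int) -> list[LayerSpec]:
    return ([_conv_spec(kernel)] * n_conv
            + [LayerSpec(kind="maxpool", pool=POOL_SIZE),
               LayerSpec(kind="dropout", rate=DROPOUT_RATE)])


def _dense_head() -> list[LayerSpec]:
    specs = [LayerSpec(kind="flatten")]
    for i, units in enumerate(DENSE_UNITS):
        act = "linear" if i == len(DENSE_UNITS) - 1 else "relu"
        specs.append(LayerSpec(kind="dense", units=units, activation=act))
    return specs


def build_stack(variant: str, input_length: int) -> LayerStack:
    """Construct a variant's layer stack, validating the input length.

    Raises :class:`ArchitectureError` naming the first layer whose output
    would be empty.
    """
    if variant == "CNN-3B3Conv":
        layers = _block(3, KERNEL_BLOCK1) + _block(3, KERNEL_BLOCK2) + _dense_head()
    elif variant == "CNN-3Conv":
        layers = _block(3, KERNEL_BLOCK1) + _dense_head()
    elif variant == "CNN-1Conv":
        layers = _block(1, KERNEL_BLOCK1) + _dense_head()
    else:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    stack = LayerStack(variant, input_length, tuple(layers))
    propagate_shapes(stack)  # raises if the length is exhausted
    return stack


def propagate_shapes(stack: LayerStack) -> list[int]:
    """Per-layer output sizes: temporal length through conv/pool layers,
    then feature count from flatten onward.

    Valid stride-1 convolution maps length n to n − kernel + 1; maxpool to
    floor(n / pool).  Raises :class:`ArchitectureError` if any layer's
    output would be shorter than 1.
    """
    size = stack.input_length
    channels = 3
    sizes: list[int] = []
    for i, spec in enumerate(stack.layers):
        if spec.kind == "conv1d":
            size = size - spec.kernel + 1
            channels = spec.filters
            if size < 1:
                raise ArchitectureError(
                    f"layer {i} (conv1d kernel {spec.kernel}) exhausts the "
                    f"temporal length for input_length {stack.input_length}")
        elif spec.kind == "maxpool":
            size = size // spec.pool
            if size < 1:
                raise ArchitectureError(
                    f"layer {i} (maxpool {spec.pool}) exhausts the temporal "
                    f"length for input_length {stack.input_length}")
        elif spec.kind == "dropout":
            pass
        elif spec.kind == "flatten":
            size = size * channels
            channels = 1
        elif spec.kind == "dense":
            size = spec.units
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
        sizes.append(size)
    return sizes


def flatten_size(stack: LayerStack) -> int:
    """Feature count entering the dense head."""
    sizes = propagate_shapes(stack)
    for spec, size in zip(stack.layers, sizes):
        if spec.kind == "flatten":
            return size
    raise ValueError("stack has no flatten layer")


def count_parameters(stack: LayerStack) -> int:
    """Total trainable weights + biases across the stack."""
    total = 0
    channels = 3
    sizes = propagate_shapes(stack)
    in_features = None
    for spec, size in zip(stack.layers, sizes):
        if spec.kind == "conv1d":
            total += spec.kernel * channels * spec.filters + spec.filters
            channels = spec.filters
        elif spec.kind == "flatten":
            in_features = size
        elif spec.kind == "dense":
            total += in_features * spec.units + spec.units
            in_features = spec.units
    return total


def logcosh_loss(predicted: Sequence[float], target: Sequence[float]) -> float:
    """Mean over components of log(cosh(predicted − target)).

    Even in the residual's sign, bounded above by mean |residual|, and
    numerically stable for large residuals.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {target.shape}")
    return float(np.mean(nn.logcosh(predicted - target)))


@dataclass
class TrainConfig:
    """The optimizer recipe: SGD with Nesterov momentum, log-cosh loss.

    Defaults are the fall-detection study settings; ``decay`` applies per
    update as lr_t = learning_rate / (1 + decay·t).
    """

    learning_rate: float = 0.0107
    momentum: float = 0.999
    decay: float = 1e-6
    nesterov: bool = True
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A layer stack plus its trained parameters and per-epoch history."""

    stack: LayerStack
    network: nn.Network
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None


def build_network(stack: LayerStack) -> nn.Network:
    """Materialize a declarative stack as a runnable (uninitialized) net."""
    layers: list[nn.Layer] = []
    channels = 3
    for spec in stack.layers:
        if spec.kind == "conv1d":
            layers.append(nn.Conv1D(channels, spec.filters, spec.kernel,
                                    l2=spec.l2 or 0.0))
            channels = spec.filters
        elif spec.kind == "maxpool":
            layers.append(nn.MaxPool1D(spec.pool))
        elif spec.kind == "dropout":
            layers.append(nn.Dropout(spec.rate))
        elif spec.kind == "flatten":
            layers.append(nn.Flatten())
        elif spec.kind == "dense":
            in_features = _dense_in_features(stack, spec)
            layers.append(nn.Dense(in_features, spec.units,
                                   activation=spec.activation or "relu"))
    return nn.Network(layers)


def _dense_in_features(stack: LayerStack, target: LayerSpec) -> int:
    sizes = propagate_shapes(stack)
    prev = None
    for spec, size in zip(stack.layers, sizes):
        if spec is target:
            return prev
        prev = size
    raise ValueError("dense spec not found in stack")


def _one_hot(labels: Sequence[str]) -> np.ndarray:
    codes = np.array([1 if l == LABEL_FALL else 0 for l in labels])
    out = np.zeros((len(codes), 2))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def train_model(stack: LayerStack, train: LabeledDataset,
                config: TrainConfig | None = None) -> TrainedModel:
    """Train a variant on normalized windows with the SGD recipe.

    Weights are Glorot-uniform initialized and the per-epoch shuffle and
    dropout masks all derive from ``config.seed``, so identical calls give
    identical loss histories.  With ``epochs=0`` the returned model carries
    its seeded initialization and an empty history.
    """
    config = config or TrainConfig()
    if len(train) == 0:
        raise ValueError("training set is empty")
    if train.window_length != stack.input_length:
        raise ValueError(
            f"window length {train.window_length} does not match stack "
            f"input_length {stack.input_length}")
    x = train.stacked()
    y = _one_hot(train.labels())

    rng = np.random.default_rng(config.seed)
    network = build_network(stack)
    network.initialize(rng)
    optimizer = nn.SGD(config.learning_rate, momentum=config.momentum,
                       decay=config.decay, nesterov=config.nesterov)

    history: list[dict] = []
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = network.forward(xb, training=True, rng=rng)
            loss, dz = nn.softmax_logcosh_loss(logits, yb)
            losses.append(loss + network.penalty())
            correct += int((logits.argmax(axis=1) == yb.argmax(axis=1)).sum())
            network.backward(dz)
            optimizer.step(network)
        history.append({
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        })
    return TrainedModel(stack=stack, network=network, history=history,
                        config=config)


@dataclass
class Prediction:
    score_adl: float
    score_fall: float
    label: str


def predict(model: TrainedModel,
            windows: LabeledDataset | Sequence[Window]) -> list[Prediction]:
    """Score windows; softmax scores sum to 1, ties break toward ADL."""
    window_list = list(windows)
    if not window_list:
        return []
    x = np.stack([w.values for w in window_list])
    if x.shape[1] != model.stack.input_length:
        raise ValueError(
            f"window length {x.shape[1]} does not match model input_length "
            f"{model.stack.input_length}")
    scores = nn.softmax(model.network.forward(x, training=False))
    out = []
    for s_adl, s_fall in scores:
        label = LABEL_FALL if s_fall > s_adl else LABEL_ADL
        out.append(Prediction(float(s_adl), float(s_fall), label))
    return out


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    """Checkpoint as ``model.json`` (architecture + history) plus
    ``weights.npz``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "stack": json.loads(model.stack.to_json()),
        "history": model.history,
        "config": asdict(model.config) if model.config else None,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))
    np.savez(directory / "weights.npz", **model.network.get_weights())
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    stack = LayerStack.from_json(json.dumps(meta["stack"]))
    network = build_network(stack)
    network.initialize(np.random.default_rng(0))
    with np.load(directory / "weights.npz") as weights:
        network.set_weights({k: weights[k] for k in weights.files})
    config = TrainConfig(**meta["config"]) if meta.get("config") else None
    return TrainedModel(stack=stack, network=network,
                        history=meta.get("history", []), config=config)
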