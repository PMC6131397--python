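"""Binary follicle/background patch classifier.

A small VGG-style convolutional network — stacks of 3x3 convolutions with
ReLU, max-pooling after each block, one fully-connected layer with dropout,
and a 2-way softmax head — trained with mini-batch gradient descent under
the Adadelta adaptive learning-rate rule on categorical cross-entropy.

The numerical stack (convolution, pooling, dense layers, backpropagation,
Adadelta, dropout) is implemented here in numpy with seeded determinism:
same seed, same weights, same predictions. Reference implementations of the
single-neuron response and the softmax normalization are exposed as plain
functions.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataset_builder import LABEL_FOLLICLE, PatchDataset
from .errors import ConfigurationError, ValidationError

# class index convention: 0 = background, 1 = follicle
CLASS_BACKGROUND = 0
CLASS_FOLLICLE = 1


# ---------------------------------------------------------------------------
# reference equations


def relu(t):
    """Rectified linear unit, max(0, t)."""
    return np.maximum(0.0, t)


def sigmoid(t):
    """Logistic sigmoid, 1/(1+e^-t)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(t, dtype=float)))


_ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid}


@dataclass
class NeuronParams:
    """Weights, bias and activation of a single artificial neuron."""

    weights: np.ndarray
    bias: float
    activation: str = "relu"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")


def neuron_response(x, params: NeuronParams) -> float:
    """Single-neuron output sigma(sum_i w_i x_i - b)."""
    x = np.asarray(x, dtype=float)
    if x.shape != params.weights.shape:
        raise ValidationError(
            f"input length {x.shape} does not match weights {params.weights.shape}"
        )
    return float(_ACTIVATIONS[params.activation](x @ params.weights - params.bias))


def softmax(z) -> np.ndarray:
    """Softmax normalization e^{z_j} / sum_k e^{z_k} of a score vector.

    Computed with max-subtraction so extreme logits cannot overflow; the
    result is a probability vector (non-negative, sums to 1).
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValidationError("softmax of an empty vector is undefined")
    shifted = z - z.max()
    e = np.exp(shifted)
    return e / e.sum()


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# architecture


@dataclass
class ArchitectureConfig:
    """Layer plan of the classifier.

    ``conv_blocks`` is an ordered list of ``(n_conv_layers, kernel_size,
    n_filters)``; each block ends in a ``pool_size`` x ``pool_size`` max-pool.
    One hidden fully-connected layer of ``fc_units`` with dropout precedes
    the ``n_classes``-way softmax output.
    """

    conv_blocks: tuple = ((2, 3, 32), (2, 3, 64), (2, 3, 128))
    pool_size: int = 2
    fc_units: int = 128
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_size: int = 48

    def __post_init__(self):
        self.conv_blocks = tuple(tuple(b) for b in self.conv_blocks)
        if not (0 <= self.dropout_rate < 1):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        size = self.input_size
        for i, (n_conv, kernel, filters) in enumerate(self.conv_blocks):
            if n_conv < 1 or filters < 1 or kernel % 2 == 0:
                raise ConfigurationError(
                    f"conv block {i}: need n_conv>=1, odd kernel, filters>=1"
                )
            if size % self.pool_size != 0:
                raise ConfigurationError(
                    f"pool after block {i}: size {size} not divisible by "
                    f"{self.pool_size}"
                )
            size //= self.pool_size
        if size < 1:
            raise ConfigurationError("pooling collapses the image to nothing")


#: Shipping presets: "tiny" trains in seconds on CPU (used throughout the
#: synthetic benchmark); "vgg-small" is a deeper 3-block stack.
PRESETS = {
    "tiny": ArchitectureConfig(
        conv_blocks=((1, 3, 8),), pool_size=4, fc_units=32, dropout_rate=0.25
    ),
    "vgg-small": ArchitectureConfig(
        conv_blocks=((2, 3, 32), (2, 3, 64), (2, 3, 128)),
        pool_size=2,
        fc_units=128,
        dropout_rate=0.5,
    ),
}


def get_preset(name: str, input_size: int = 48) -> ArchitectureConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    base = PRESETS[name]
    return ArchitectureConfig(
        conv_blocks=base.conv_blocks,
        pool_size=base.pool_size,
        fc_units=base.fc_units,
        dropout_rate=base.dropout_rate,
        n_classes=base.n_classes,
        input_size=input_size,
    )


@dataclass
class TrainingConfig:
    """Mini-batch Adadelta training parameters."""

    batch_size: int = 32
    epochs: int = 10
    rho: float = 0.95
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")


@dataclass
class ClassifierModel:
    """Architecture plus opaque parameter state and training history."""

    architecture: ArchitectureConfig
    layers: list
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})

    def copy(self) -> "ClassifierModel":
        return copy.deepcopy(self)

    def parameters(self):
        """Yield (layer, key) pairs for every trainable array."""
        for layer in self.layers:
            for key in ("W", "b"):
                if key in layer:
                    yield layer, key


def build_classifier(arch, seed: int = 0) -> ClassifierModel:
    """Construct an untrained model with seeded He-normal initialization.

    ``arch`` is an :class:`ArchitectureConfig` or a preset name
    (``"tiny"``, ``"vgg-small"``).
    """
    if isinstance(arch, str):
        arch = get_preset(arch)
    rng = np.random.default_rng(seed)
    layers: list[dict] = []
    channels = 1
    size = arch.input_size
    for n_conv, kernel, filters in arch.conv_blocks:
        for _ in range(n_conv):
            std = np.sqrt(2.0 / (channels * kernel * kernel))
            layers.append(
                {
                    "type": "conv",
                    "W": rng.normal(0.0, std, (filters, channels, kernel, kernel)),
                    "b": np.zeros(filters),
                }
            )
            layers.append({"type": "relu"})
            channels = filters
        layers.append({"type": "pool", "size": arch.pool_size})
        size //= arch.pool_size
    layers.append({"type": "flatten"})
    flat = channels * size * size
    std = np.sqrt(2.0 / flat)
    layers.append(
        {"type": "dense", "W": rng.normal(0.0, std, (flat, arch.fc_units)),
         "b": np.zeros(arch.fc_units)}
    )
    layers.append({"type": "relu"})
    layers.append({"type": "dropout", "rate": arch.dropout_rate})
    std = np.sqrt(2.0 / arch.fc_units)
    layers.append(
        {"type": "dense", "W": rng.normal(0.0, std, (arch.fc_units, arch.n_classes)),
         "b": np.zeros(arch.n_classes)}
    )
    return ClassifierModel(architecture=arch, layers=layers)


# ---------------------------------------------------------------------------
# layer forward/backward


def _conv_forward(x, W, b):
    k = W.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    y = np.einsum("nchwij,fcij->nfhw", win, W, optimize=True)
    y += b[None, :, None, None]
    return y, (xp, W, k, p)


def _conv_backward(dy, cache):
    xp, W, k, p = cache
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    dW = np.einsum("nchwij,nfhw->fcij", win, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
    dwin = sliding_window_view(dyp, (k, k), axis=(2, 3))
    wflip = W[:, :, ::-1, ::-1]
    dx = np.einsum("nfhwij,fcij->nchw", dwin, wflip, optimize=True)
    return dx, dW, db


def _pool_forward(x, s):
    n, c, h, w = x.shape
    xr = (
        x.reshape(n, c, h // s, s, w // s, s)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // s, w // s, s * s)
    )
    am = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
    return y, (am, s, x.shape)


def _pool_backward(dy, cache):
    am, s, shape = cache
    n, c, h, w = shape
    dxr = np.zeros((n, c, h // s, w // s, s * s))
    np.put_along_axis(dxr, am[..., None], dy[..., None], axis=-1)
    dx = (
        dxr.reshape(n, c, h // s, w // s, s, s)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )
    return dx


def _forward(model, x, training=False, rng=None):
    """Run the stack; returns logits and per-layer caches for backprop."""
    caches = []
    for layer in model.layers:
        kind = layer["type"]
        if kind == "conv":
            x, cache = _conv_forward(x, layer["W"], layer["b"])
            caches.append(cache)
        elif kind == "relu":
            caches.append(x > 0)
            x = np.maximum(0.0, x)
        elif kind == "pool":
            x, cache = _pool_forward(x, layer["size"])
            caches.append(cache)
        elif kind == "flatten":
            caches.append(x.shape)
            x = x.reshape(x.shape[0], -1)
        elif kind == "dense":
            caches.append(x)
            x = x @ layer["W"] + layer["b"]
        elif kind == "dropout":
            if training and layer["rate"] > 0:
                mask = (rng.random(x.shape) >= layer["rate"]) / (1 - layer["rate"])
                caches.append(mask)
                x = x * mask
            else:
                caches.append(None)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown layer type {kind!r}")
    return x, caches


def _backward(model, caches, dlogits):
    """Backpropagate; returns list of (layer, {param: grad})."""
    grads = []
    dx = dlogits
    for layer, cache in zip(reversed(model.layers), reversed(caches)):
        kind = layer["type"]
        if kind == "conv":
            dx, dW, db = _conv_backward(dx, cache)
            grads.append((layer, {"W": dW, "b": db}))
        elif kind == "relu":
            dx = dx * cache
        elif kind == "pool":
            dx = _pool_backward(dx, cache)
        elif kind == "flatten":
            dx = dx.reshape(cache)
        elif kind == "dense":
            x = cache
            grads.append((layer, {"W": x.T @ dx, "b": dx.sum(axis=0)}))
            dx = dx @ layer["W"].T
        elif kind == "dropout":
            if cache is not None:
                dx = dx * cache
    return grads


def _prepare_patches(patches) -> np.ndarray:
    """Stack patches into an (N,1,H,W) float array scaled to [-0.5, 0.5]."""
    if isinstance(patches, PatchDataset):
        arrays = [p.pixels for p in patches.patches]
    elif isinstance(patches, np.ndarray) and patches.ndim == 3:
        arrays = list(patches)
    else:
        arrays = [p.pixels if hasattr(p, "pixels") else np.asarray(p) for p in patches]
    if not arrays:
        return np.empty((0, 1, 0, 0))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError(f"patches have mixed shapes: {sorted(shapes)}")
    x = np.stack(arrays).astype(np.float64) / 255.0 - 0.5
    return x[:, None, :, :]


def train(model: ClassifierModel, data: PatchDataset, cfg: TrainingConfig) -> ClassifierModel:
    """Seeded mini-batch Adadelta training on categorical cross-entropy.

    Returns a new model (the input is untouched); ``epochs = 0`` returns an
    identical copy. The history records per-epoch mean training loss and
    accuracy and extends across successive calls, so hard-negative
    retraining continues the same curve.
    """
    if len(data) == 0:
        raise ValidationError("cannot train on an empty dataset")
    model = model.copy()
    if cfg.epochs == 0:
        return model

    x = _prepare_patches(data)
    size = model.architecture.input_size
    if x.shape[2] != size or x.shape[3] != size:
        raise ValidationError(
            f"patch size {x.shape[2]}x{x.shape[3]} does not match model input {size}"
        )
    y = np.array(
        [CLASS_FOLLICLE if p.label == LABEL_FOLLICLE else CLASS_BACKGROUND
         for p in data.patches]
    )
    n = len(y)
    n_classes = model.architecture.n_classes
    rng = np.random.default_rng(cfg.seed)

    # Adadelta accumulators: E[g^2] and E[dx^2] per trainable array
    acc = {}
    for layer, key in model.parameters():
        acc[(id(layer), key)] = [np.zeros_like(layer[key]), np.zeros_like(layer[key])]

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits, caches = _forward(model, xb, training=True, rng=rng)
            probs = _softmax_rows(logits)
            eps = 1e-12
            losses.append(float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))))
            correct += int((probs.argmax(axis=1) == yb).sum())
            onehot = np.zeros((len(yb), n_classes))
            onehot[np.arange(len(yb)), yb] = 1.0
            dlogits = (probs - onehot) / len(yb)
            grads = _backward(model, caches, dlogits)
            for layer, gdict in grads:
                for key, g in gdict.items():
                    eg, edx = acc[(id(layer), key)]
                    eg *= cfg.rho
                    eg += (1 - cfg.rho) * g * g
                    step = -np.sqrt(edx + cfg.epsilon) / np.sqrt(eg + cfg.epsilon) * g
                    edx *= cfg.rho
                    edx += (1 - cfg.rho) * step * step
                    layer[key] += step
        model.history["loss"].append(float(np.mean(losses)))
        model.history["accuracy"].append(correct / n)
    return model


def predict_proba(model: ClassifierModel, patches, chunk_size: int = 256) -> np.ndarray:
    """Follicle-class probability for each patch (dropout disabled).

    Scoring is chunked for memory; the result is independent of
    ``chunk_size``.
    """
    x = _prepare_patches(patches)
    if x.shape[0] == 0:
        return np.empty(0)
    size = model.architecture.input_size
    if x.shape[2] != size or x.shape[3] != size:
        raise ValidationError(
            f"patch size {x.shape[2]}x{x.shape[3]} does not match model input {size}"
        )
    out = []
    for start in range(0, x.shape[0], chunk_size):
        logits, _ = _forward(model, x[start : start + chunk_size], training=False)
        out.append(_softmax_rows(logits)[:, CLASS_FOLLICLE])
    return np.concatenate(out)


def predict_proba_full(model: ClassifierModel, patches, chunk_size: int = 256) -> np.ndarray:
    """Full softmax output, one probability row per patch."""
    x = _prepare_patches(patches)
    if x.shape[0] == 0:
        return np.empty((0, model.architecture.n_classes))
    out = []
    for start in range(0, x.shape[0], chunk_size):
        logits, _ = _forward(model, x[start : start + chunk_size], training=False)
        out.append(_softmax_rows(logits))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ClassifierModel, path) -> None:
    """Save architecture, weights and history to one .npz checkpoint."""
    arch = model.architecture
    meta = {
        "conv_blocks": arch.conv_blocks,
        "pool_size": arch.pool_size,
        "fc_units": arch.fc_units,
        "dropout_rate": arch.dropout_rate,
        "n_classes": arch.n_classes,
        "input_size": arch.input_size,
        "history": model.history,
    }
    arrays = {}
    for i, layer in enumerate(model.layers):
        for key in ("W", "b"):
            if key in layer:
                arrays[f"{i}_{key}"] = layer[key]
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arch = ArchitectureConfig(
            conv_blocks=tuple(tuple(b) for b in meta["conv_blocks"]),
            pool_size=meta["pool_size"],
            fc_units=meta["fc_units"],
            dropout_rate=meta["dropout_rate"],
            n_classes=meta["n_classes"],
            input_size=meta["input_size"],
        )
        model = build_classifier(arch, seed=0)
        for i, layer in enumerate(model.layers):
            for key in ("W", "b"):
                if key in layer:
                    layer[key] = data[f"{i}_{key}"]
        model.history = meta["history"]
    return model
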