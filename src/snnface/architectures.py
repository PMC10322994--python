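"""Shallow convolutional models of the subcortical face pathway.

One parameterized model family covers all nine studied variants.  The base
shallow network (SNN) is two convolution + max-pooling + local-response-
normalization blocks followed by two fully connected layers::

    input 227×227×3
    → conv1 11×11/stride 4 (fixed analytic bank, 32 ch) → ReLU
    → max-pool (5×5/stride 4, ceil mode) → LRN
    → conv2 5×5/stride 1/pad 2 (64 ch) → ReLU
    → max-pool → LRN
    → FC1 (32) → ReLU → dropout 0.5 → FC2 (7) → softmax

Cortical-replacement variants change the first-layer filter family (DoG →
Gabor), insert a trainable 3×3 convolution after each of the first two
convolutions ("add-layer"), and/or narrow the pooling geometry (5×5/4 →
3×3/2).  The first convolution layer is always frozen: its weights are the
analytic bank and are never updated by training.

Layers are implemented in NumPy (float32); convolutions are im2col + BLAS
matmul, pooling is ceiling-mode ("cover-all") with overhanging windows padded
by −inf, and LRN is the cross-channel divisive normalization
``b_c = a_c / (k + α Σ_{j∈win(c,n)} a_j²)^β`` with the window truncated at
channel boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .filter_banks import FilterKernel, bank_to_conv_weights

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Full description of one model variant."""

    filter_family: str = "dog"  # {dog, gabor}
    depth: str = "shallow"  # {shallow, deep}
    pool_window: int = 5
    pool_stride: int = 4
    lrn_k: float = 1.0
    lrn_n: int = 5
    lrn_alpha: float = 2e-5
    lrn_beta: float = 0.75
    dropout_rate: float = 0.5
    input_size: int = 227
    in_channels: int = 3
    conv1_channels: int = 32
    conv1_kernel: int = 11
    conv1_stride: int = 4
    conv2_channels: int = 64
    conv2_kernel: int = 5
    fc1_units: int = 32
    n_classes: int = 7

    def __post_init__(self) -> None:
        if self.filter_family not in ("dog", "gabor"):
            raise ValueError(f"unknown filter family {self.filter_family!r}")
        if self.depth not in ("shallow", "deep"):
            raise ValueError(f"depth must be 'shallow' or 'deep', got {self.depth!r}")
        if self.lrn_n % 2 == 0:
            raise ValueError("LRN window size n must be odd")


#: The nine named variants studied.
PRESETS: dict[str, ModelConfig] = {
    "snn": ModelConfig(),
    "narrow-pooling": ModelConfig(pool_window=3, pool_stride=2),
    "gabor": ModelConfig(filter_family="gabor"),
    "add-layer": ModelConfig(depth="deep"),
    "narrow-pooling+gabor": ModelConfig(filter_family="gabor", pool_window=3, pool_stride=2),
    "gabor+add-layer": ModelConfig(filter_family="gabor", depth="deep"),
    "narrow-pooling+add-layer": ModelConfig(depth="deep", pool_window=3, pool_stride=2),
    "full-replacement": ModelConfig(
        filter_family="gabor", depth="deep", pool_window=3, pool_stride=2
    ),
    "stride-2": ModelConfig(pool_window=5, pool_stride=2),
}


def preset(name: str, **overrides) -> ModelConfig:
    """Look up a named variant, optionally overriding fields."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Shape arithmetic
# ---------------------------------------------------------------------------


def _conv_out(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def _pool_out(size: int, window: int, stride: int) -> int:
    # ceiling mode: overhanging windows produce an extra output
    return int(math.ceil((size - window) / stride)) + 1


@dataclass(frozen=True)
class LayerShapes:
    """Spatial resolution and channel count after each stage."""

    shapes: dict = field(default_factory=dict)  # name -> (channels, H, W) or (units,)

    def units(self, name: str) -> int:
        return int(np.prod(self.shapes[name]))

    def __getitem__(self, name):
        return self.shapes[name]


def compute_layer_shapes(config: ModelConfig) -> LayerShapes:
    """Resolutions through the network; rejects configs that collapse to <=0.

    conv1 uses valid (no-padding) sizing with its stride; conv2 and the added
    3×3 layers use resolution-preserving padding; pooling uses ceiling-mode
    sizing ``out = ceil((in − window)/stride) + 1``.
    """
    shapes: dict = {"input": (config.in_channels, config.input_size, config.input_size)}
    s = _conv_out(config.input_size, config.conv1_kernel, config.conv1_stride, pad=0)
    if s <= 0:
        raise ValueError(f"conv1 output collapsed to {s} <= 0")
    shapes["conv1"] = (config.conv1_channels, s, s)
    if config.depth == "deep":
        shapes["conv1b"] = (config.conv1_channels, s, s)  # 3×3/1/1 preserves resolution
    s = _pool_out(s, config.pool_window, config.pool_stride)
    if s <= 0:
        raise ValueError(f"pool1 output collapsed to {s} <= 0")
    shapes["pool1"] = (config.conv1_channels, s, s)
    shapes["conv2"] = (config.conv2_channels, s, s)  # resolution-preserving padding
    if config.depth == "deep":
        shapes["conv2b"] = (config.conv2_channels, s, s)
    s = _pool_out(s, config.pool_window, config.pool_stride)
    if s <= 0:
        raise ValueError(f"pool2 output collapsed to {s} <= 0")
    shapes["pool2"] = (config.conv2_channels, s, s)
    shapes["fc1"] = (config.fc1_units,)
    shapes["fc2"] = (config.n_classes,)
    return LayerShapes(shapes)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    name: str = ""
    trainable: bool = False

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> Optional[np.ndarray]:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """im2col convolution, NCHW layout, float32."""

    def __init__(self, name, in_ch, out_ch, kernel, stride=1, pad=0, trainable=True):
        self.name = name
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        self.trainable = trainable
        self.W = np.zeros((out_ch, in_ch, kernel, kernel), np.float32)
        self.b = np.zeros(out_ch, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def forward(self, x, train=False, rng=None):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = x.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, ho, wo, c*k*k) contiguous copy for BLAS
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * k * k)
        out = cols.reshape(-1, c * k * k) @ self.W.reshape(len(self.W), -1).T
        out += self.b
        if train and self.trainable:
            self._cols = cols
            self._x_shape = (n, c, h, w)
        elif train:
            self._x_shape = (n, c, h, w)
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(out)

    def backward(self, dout, need_dx=True):
        n, co, ho, wo = dout.shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, co)
        if self.trainable:
            cols2d = self._cols.reshape(-1, self._cols.shape[-1])
            self.dW[...] = (dmat.T @ cols2d).reshape(self.W.shape)
            self.db[...] = dmat.sum(axis=0)
        if not need_dx:
            return None
        k, s, p = self.kernel, self.stride, self.pad
        nh, c, h, w = self._x_shape
        dcols = (dmat @ self.W.reshape(co, -1)).reshape(n, ho, wo, c, k, k)
        dx = np.zeros(self._x_shape, np.float32)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki : ki + ho * s : s, kj : kj + wo * s : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def __init__(self, name):
        self.name = name
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout, need_dx=True):
        return dout * self._mask if need_dx else None


class MaxPool(Layer):
    """Ceiling-mode max pooling; overhanging windows see −inf padding."""

    def __init__(self, name, window, stride):
        self.name = name
        self.window = window
        self.stride = stride
        self._arg = None
        self._shape = None

    def _padded(self, x):
        n, c, h, w = x.shape
        ho = _pool_out(h, self.window, self.stride)
        wo = _pool_out(w, self.window, self.stride)
        need_h = (ho - 1) * self.stride + self.window
        need_w = (wo - 1) * self.stride + self.window
        if need_h > h or need_w > w:
            x = np.pad(
                x,
                ((0, 0), (0, 0), (0, need_h - h), (0, need_w - w)),
                constant_values=-np.inf,
            )
        return x, ho, wo

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        xp, ho, wo = self._padded(x)
        k, s = self.window, self.stride
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        if train:
            self._arg = flat.argmax(axis=-1)
            self._padded_shape = xp.shape
            out = np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]
        else:
            out = flat.max(axis=-1)
        return np.ascontiguousarray(out)

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        n, c, hp, wp = self._padded_shape
        k, s = self.window, self.stride
        ho, wo = dout.shape[2], dout.shape[3]
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        row = ii[None, None] * s + self._arg // k
        col = jj[None, None] * s + self._arg % k
        flat_idx = (
            (np.arange(n)[:, None, None, None] * c + np.arange(c)[None, :, None, None]) * hp + row
        ) * wp + col
        dxp = np.zeros(n * c * hp * wp, np.float32)
        np.add.at(dxp, flat_idx.ravel(), dout.ravel())
        dxp = dxp.reshape(n, c, hp, wp)
        h, w = self._shape[2], self._shape[3]
        return dxp[:, :, :h, :w]


def _channel_window_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Sum over a centered cross-channel window of size n, truncated at edges.

    x has channels on axis 1.
    """
    half = n // 2
    c = x.shape[1]
    cs = np.concatenate(
        [np.zeros_like(x[:, :1]), np.cumsum(x, axis=1)], axis=1
    )  # cs[:, j] = sum of first j channels
    lo = np.maximum(np.arange(c) - half, 0)
    hi = np.minimum(np.arange(c) + half + 1, c)
    return cs[:, hi] - cs[:, lo]


class LRN(Layer):
    """Cross-channel local response normalization (pure per-position op)."""

    def __init__(self, name, k=1.0, n=5, alpha=2e-5, beta=0.75):
        self.name = name
        self.k = k
        self.n = n
        self.alpha = alpha
        self.beta = beta

    def forward(self, x, train=False, rng=None):
        S = self.k + self.alpha * _channel_window_sum(x * x, self.n)
        out = x * S ** (-self.beta)
        if train:
            self._x = x
            self._S = S
        return out

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        x, S = self._x, self._S
        T = dout * x * S ** (-self.beta - 1.0)
        return dout * S ** (-self.beta) - 2.0 * self.alpha * self.beta * x * _channel_window_sum(
            T, self.n
        )


class Flatten(Layer):
    def __init__(self, name):
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout, need_dx=True):
        return dout.reshape(self._shape) if need_dx else None


class Dense(Layer):
    def __init__(self, name, in_units, out_units):
        self.name = name
        self.trainable = True
        self.W = np.zeros((in_units, out_units), np.float32)
        self.b = np.zeros(out_units, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout, need_dx=True):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T if need_dx else None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, name, rate):
        self.name = name
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class Model:
    """A layer stack plus its config and frozen first-layer bank."""

    def __init__(self, config: ModelConfig, layers: list[Layer], bank: list[FilterKernel]):
        self.config = config
        self.layers = layers
        self.bank = bank
        self.shapes = compute_layer_shapes(config)

    # -- construction helpers -------------------------------------------------

    def layer(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def first_trainable_index(self) -> int:
        for i, lyr in enumerate(self.layers):
            if lyr.trainable:
                return i
        raise RuntimeError("model has no trainable layer")

    def trainable_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.trainable]

    def conv1_weights(self) -> np.ndarray:
        return self.layer("conv1").W

    # -- execution -------------------------------------------------------------

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        n = self.config.input_size
        if batch.ndim == 3:
            batch = batch[None]
        if batch.ndim != 4 or batch.shape[1:] != (n, n, self.config.in_channels):
            raise ValueError(
                f"expected batch of shape (N, {n}, {n}, {self.config.in_channels}), "
                f"got {batch.shape}"
            )
        return np.ascontiguousarray(batch.transpose(0, 3, 1, 2), dtype=np.float32)

    def forward(
        self,
        batch: np.ndarray,
        train: bool = False,
        rng=None,
        record: Optional[list[str]] = None,
        start: int = 0,
        raw: bool = False,
    ):
        """Run the stack; returns (probabilities, records).

        ``record`` names layers whose outputs are captured (e.g. ["conv1",
        "pool1", "fc1"]).  ``start`` > 0 feeds ``batch`` directly into layer
        index ``start`` (used with cached frozen features); ``raw`` skips the
        NHWC input check in that case.
        """
        x = batch if (start > 0 or raw) else self._check_batch(batch)
        x = np.asarray(x, np.float32)
        records: dict[str, np.ndarray] = {}
        for lyr in self.layers[start:]:
            x = lyr.forward(x, train=train, rng=rng)
            if record and lyr.name in record:
                records[lyr.name] = x
        return softmax(x), records

    def logits(self, batch: np.ndarray, train=False, rng=None, start: int = 0) -> np.ndarray:
        x = batch if start > 0 else self._check_batch(batch)
        x = np.asarray(x, np.float32)
        for lyr in self.layers[start:]:
            x = lyr.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray, start: int = 0) -> None:
        """Backpropagate from the logits down to layer index ``start``."""
        d = dlogits
        for i in range(len(self.layers) - 1, start - 1, -1):
            d = self.layers[i].backward(d, need_dx=(i > start))

    # -- serialization ----------------------------------------------------------

    def save_weights(self, path) -> None:
        arrays = {}
        for i, lyr in enumerate(self.layers):
            for j, p in enumerate(lyr.params()):
                arrays[f"{i}:{lyr.name}:{j}"] = p
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for key in data.files:
                i, _, j = key.split(":")
                self.layers[int(i)].params()[int(j)][...] = data[key]


def build_model(config: ModelConfig, filter_bank: list[FilterKernel]) -> Model:
    """Assemble a model variant around its fixed first-layer bank."""
    if len(filter_bank) != config.conv1_channels:
        raise ValueError(
            f"bank has {len(filter_bank)} kernels, config wants {config.conv1_channels}"
        )
    families = {f.family for f in filter_bank}
    if families != {config.filter_family}:
        raise ValueError(f"bank families {families} do not match config {config.filter_family!r}")

    shapes = compute_layer_shapes(config)
    c = config
    layers: list[Layer] = []

    conv1 = Conv2D(
        "conv1", c.in_channels, c.conv1_channels, c.conv1_kernel, c.conv1_stride, 0, False
    )
    conv1.W[...] = bank_to_conv_weights(filter_bank, c.in_channels)
    layers += [conv1, ReLU("relu1")]
    if c.depth == "deep":
        layers += [
            Conv2D("conv1b", c.conv1_channels, c.conv1_channels, 3, 1, 1, True),
            ReLU("relu1b"),
        ]
    layers += [
        MaxPool("pool1", c.pool_window, c.pool_stride),
        LRN("lrn1", c.lrn_k, c.lrn_n, c.lrn_alpha, c.lrn_beta),
        Conv2D(
            "conv2",
            c.conv1_channels,
            c.conv2_channels,
            c.conv2_kernel,
            1,
            (c.conv2_kernel - 1) // 2,
            True,
        ),
        ReLU("relu2"),
    ]
    if c.depth == "deep":
        layers += [
            Conv2D("conv2b", c.conv2_channels, c.conv2_channels, 3, 1, 1, True),
            ReLU("relu2b"),
        ]
    layers += [
        MaxPool("pool2", c.pool_window, c.pool_stride),
        LRN("lrn2", c.lrn_k, c.lrn_n, c.lrn_alpha, c.lrn_beta),
        Flatten("flatten"),
        Dense("fc1", shapes.units("pool2"), c.fc1_units),
        ReLU("relu_fc1"),
        Dropout("dropout", c.dropout_rate),
        Dense("fc2", c.fc1_units, c.n_classes),
    ]
    return Model(config, layers, filter_bank)
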