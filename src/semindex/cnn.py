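"""Convolutional feature extractor over document matrices.

Geometry
--------
A document matrix of shape ``L x 4d`` is viewed as a tensor of
``(positions=L, slots=4, depth=d)``: each row stacks four d-length
sub-vectors.  First-layer kernels span ``h`` positions by the full
sub-vector depth ``d`` and slide down positions with stride 1 and across
sub-vector slots with stride ``d`` — a window never straddles two word
embeddings.  Deeper layers follow the same pattern with depth equal to the
previous layer's kernel count.  Internally activations are batched as
``(N, positions, slots, channels)``.

Each convolution is followed by k-max pooling (the k largest values per
slot/channel column, original order preserved, then gain, bias and
activation), the final stage is flattened and pushed through
fully-connected layers, with inverted dropout between layers in training
mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dbm import sigmoid

__all__ = [
    "relu",
    "dropout",
    "ConvLayerParams",
    "PoolLayerParams",
    "FCLayerParams",
    "CNNConfig",
    "conv_forward",
    "pool_forward",
    "fc_forward",
    "CNN",
    "cnn_forward",
    "default_config",
]

ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda pre: (pre > 0).astype(float)),
    "sigmoid": (sigmoid, lambda pre: sigmoid(pre) * (1.0 - sigmoid(pre))),
    "identity": (lambda x: x, lambda pre: np.ones_like(pre)),
}


def relu(x):
    """max(x, 0), elementwise."""
    return np.maximum(x, 0.0)


def dropout(tensor, rate: float, mode: str = "train", rng=None):
    """Inverted dropout.

    In training mode each unit is zeroed independently with probability
    ``rate`` and survivors are scaled by ``1/(1-rate)``, so inference is the
    identity (the expected "mean network").
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    tensor = np.asarray(tensor, dtype=float)
    if mode == "inference" or rate == 0.0:
        return tensor
    if mode != "train":
        raise ValueError(f"unknown dropout mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    mask = rng.random(tensor.shape) >= rate
    return tensor * mask / (1.0 - rate)


# ---------------------------------------------------------------------------
# layer parameter containers + functional forward ops
# ---------------------------------------------------------------------------

@dataclass
class ConvLayerParams:
    """Kernels of shape (n_kernels, h, depth) and one bias per kernel."""

    kernels: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.kernels.ndim != 3:
            raise ValueError("kernels must have shape (n_kernels, h, depth)")
        if self.bias.shape != (self.kernels.shape[0],):
            raise ValueError("one bias per kernel required")


@dataclass
class PoolLayerParams:
    """k-max pooling with per-channel gain beta and bias."""

    k: int
    beta: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.beta = np.asarray(self.beta, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)


@dataclass
class FCLayerParams:
    weight: np.ndarray
    bias: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weight.shape[0] != self.bias.shape[0]:
            raise ValueError("weight rows must match bias length")


@dataclass
class CNNConfig:
    """(conv, pool) stage specs plus FC sizes.

    ``stages`` is a list of dicts with keys ``h`` (kernel height),
    ``n_kernels`` and ``k`` (pooling); ``fc_sizes`` lists the FC output
    widths; the last FC layer uses a sigmoid, hidden layers ReLU.
    """

    stages: list[dict] = field(
        default_factory=lambda: [
            {"h": 2, "n_kernels": 8, "k": 1} for _ in range(5)
        ]
    )
    fc_sizes: list[int] = field(default_factory=lambda: [64, 48, 32])
    dropout_rate: float = 0.5
    activation: str = "relu"


def _conv_windows(x: np.ndarray, h: int) -> np.ndarray:
    # x: (N, P, S, C) -> windows (N, P-h+1, S, C, h)
    return sliding_window_view(x, h, axis=1)


def conv_forward(A: np.ndarray, layer: ConvLayerParams, activation: str = "relu"):
    """Forward convolution of a single input matrix or tensor.

    ``A`` may be 2-D ``(P, W)`` — interpreted as slots of width equal to the
    kernel depth, i.e. feature-axis stride d — or 3-D ``(P, S, C)``.
    Returns an array of feature maps with shape ``(n_kernels, P-h+1, S)``.
    """
    act, _ = ACTIVATIONS[activation]
    A = np.asarray(A, dtype=float)
    n_k, h, depth = layer.kernels.shape
    if A.ndim == 2:
        P, W = A.shape
        if W % depth != 0:
            raise ValueError("feature width must be a multiple of kernel depth")
        A = A.reshape(P, W // depth, depth)
    if A.shape[2] != depth:
        raise ValueError("input depth does not match kernel depth")
    if h > A.shape[0]:
        raise ValueError("kernel height exceeds position count")
    win = _conv_windows(A[None], h)  # (1, P', S, C, h)
    pre = np.einsum("npsch,khc->npsk", win, layer.kernels) + layer.bias
    return np.moveaxis(act(pre[0]), -1, 0)  # (n_k, P', S)


def pool_forward(feature_map: np.ndarray, layer: PoolLayerParams, activation: str = "identity"):
    """k-max pooling of one feature map (1-D or (P, S)) along positions."""
    act, _ = ACTIVATIONS[activation]
    fmap = np.asarray(feature_map, dtype=float)
    squeeze = fmap.ndim == 1
    if squeeze:
        fmap = fmap[:, None]
    P = fmap.shape[0]
    if layer.k > P:
        raise ValueError("k exceeds feature-map length")
    idx = np.argpartition(-fmap, layer.k - 1, axis=0)[: layer.k]
    idx = np.sort(idx, axis=0)  # preserve original order
    pooled = np.take_along_axis(fmap, idx, axis=0)
    out = act(np.asarray(layer.beta) * pooled + np.asarray(layer.bias))
    return out[:, 0] if squeeze else out


def fc_forward(vector: np.ndarray, layer: FCLayerParams):
    """f(W x + b) for a single vector."""
    vector = np.asarray(vector, dtype=float)
    if layer.weight.shape[1] != vector.shape[0]:
        raise ValueError("shape mismatch in fully-connected layer")
    act, _ = ACTIVATIONS[layer.activation]
    return act(layer.weight @ vector + layer.bias)


# ---------------------------------------------------------------------------
# trainable batched network
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, n_kernels, h, depth, rng, activation):
        scale = 1.0 / np.sqrt(h * depth)
        self.K = rng.normal(0.0, scale, size=(n_kernels, h, depth))
        self.b = np.zeros(n_kernels)
        self.activation = activation

    def forward(self, x):
        # x: (N, P, S, C)
        h = self.K.shape[1]
        if h > x.shape[1]:
            raise ValueError("kernel height exceeds position count")
        self._win = _conv_windows(x, h)
        self._in_shape = x.shape
        self._pre = (
            np.einsum("npsch,khc->npsk", self._win, self.K) + self.b
        )
        act, _ = ACTIVATIONS[self.activation]
        return act(self._pre)

    def backward(self, gout):
        _, dact = ACTIVATIONS[self.activation]
        dpre = gout * dact(self._pre)
        self.gK = np.einsum("npsch,npsk->khc", self._win, dpre)
        self.gb = dpre.sum(axis=(0, 1, 2))
        N, P, S, C = self._in_shape
        h = self.K.shape[1]
        gin = np.zeros(self._in_shape)
        for u in range(h):
            gin[:, u : u + P - h + 1] += np.einsum(
                "npsk,kc->npsc", dpre, self.K[:, u, :]
            )
        return gin

    def params(self):
        return [("K", self.K, "gK"), ("b", self.b, "gb")]


class _Pool:
    def __init__(self, k, n_channels, activation="identity"):
        self.k = k
        self.beta = np.ones(n_channels)
        self.b = np.zeros(n_channels)
        self.activation = activation

    def forward(self, x):
        # x: (N, P, S, C)
        if self.k > x.shape[1]:
            raise ValueError("k exceeds feature-map length")
        idx = np.argpartition(-x, self.k - 1, axis=1)[:, : self.k]
        self._idx = np.sort(idx, axis=1)
        self._pooled = np.take_along_axis(x, self._idx, axis=1)
        self._in_shape = x.shape
        self._pre = self.beta * self._pooled + self.b
        act, _ = ACTIVATIONS[self.activation]
        return act(self._pre)

    def backward(self, gout):
        _, dact = ACTIVATIONS[self.activation]
        dpre = gout * dact(self._pre)
        self.gbeta = (dpre * self._pooled).sum(axis=(0, 1, 2))
        self.gb = dpre.sum(axis=(0, 1, 2))
        gin = np.zeros(self._in_shape)
        np.put_along_axis(gin, self._idx, dpre * self.beta, axis=1)
        return gin

    def params(self):
        return [("beta", self.beta, "gbeta"), ("b", self.b, "gb")]


class _Dense:
    def __init__(self, n_out, n_in, rng, activation):
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.activation = activation

    def forward(self, x):
        self._x = x
        self._pre = x @ self.W.T + self.b
        act, _ = ACTIVATIONS[self.activation]
        return act(self._pre)

    def backward(self, gout):
        _, dact = ACTIVATIONS[self.activation]
        dpre = gout * dact(self._pre)
        self.gW = dpre.T @ self._x
        self.gb = dpre.sum(axis=0)
        return dpre @ self.W

    def params(self):
        return [("W", self.W, "gW"), ("b", self.b, "gb")]


class _Dropout:
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class CNN:
    """Batched convolutional network producing the feature vector ``y_c``.

    Construction is seeded and deterministic; ``forward`` in inference mode
    is a pure function of its input.
    """

    def __init__(self, config: CNNConfig, L: int, d: int, seed: int = 0):
        self.config = config
        self.L = L
        self.d = d
        rng = np.random.default_rng(seed)
        self.stages: list[tuple[_Conv, _Dropout, _Pool]] = []
        positions, slots, depth = L, 4, d
        for spec in config.stages:
            h = min(spec["h"], positions)
            conv = _Conv(spec["n_kernels"], h, depth, rng, config.activation)
            positions = positions - h + 1
            k = min(spec["k"], positions)
            pool = _Pool(k, spec["n_kernels"])
            self.stages.append((conv, _Dropout(config.dropout_rate), pool))
            positions, depth = k, spec["n_kernels"]
        flat = positions * slots * depth
        self.fc: list[tuple[_Dense, _Dropout]] = []
        n_in = flat
        for i, size in enumerate(config.fc_sizes):
            last = i == len(config.fc_sizes) - 1
            act = "sigmoid" if last else config.activation
            dense = _Dense(size, n_in, rng, act)
            drop = _Dropout(0.0 if last else config.dropout_rate)
            self.fc.append((dense, drop))
            n_in = size

    @property
    def output_dim(self) -> int:
        return self.config.fc_sizes[-1]

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """X: (N, L, 4, d) or a single (L, 4*d) matrix.  Returns (N, |y_c|)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X.reshape(1, X.shape[0], 4, self.d)
        if train and rng is None:
            rng = np.random.default_rng()
        x = X
        for conv, drop, pool in self.stages:
            x = pool.forward(drop.forward(conv.forward(x), train, rng))
        self._flat_shape = x.shape
        x = x.reshape(x.shape[0], -1)
        for dense, drop in self.fc:
            x = drop.forward(dense.forward(x), train, rng)
        return x[0] if single else x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backprop a gradient w.r.t. y_c; stores parameter gradients."""
        g = gy
        for dense, drop in reversed(self.fc):
            g = dense.backward(drop.backward(g))
        g = g.reshape(self._flat_shape)
        for conv, drop, pool in reversed(self.stages):
            g = conv.backward(drop.backward(pool.backward(g)))
        return g

    def _layers(self):
        for conv, _, pool in self.stages:
            yield conv
            yield pool
        for dense, _ in self.fc:
            yield dense

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for (_, p, _) in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [
            getattr(layer, gname)
            for layer in self._layers()
            for (_, _, gname) in layer.params()
        ]

    def sgd_step(self, lr: float) -> None:
        for layer in self._layers():
            for name, param, gname in layer.params():
                param -= lr * getattr(layer, gname)

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            for name, param, _ in layer.params():
                out[f"layer{i}_{name}"] = param
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for name, param, _ in layer.params():
                param[...] = state[f"layer{i}_{name}"]


def cnn_forward(doc_matrix, cnn: CNN, mode: str = "inference", rng=None) -> np.ndarray:
    """Run one document matrix (L x 4d) through the network."""
    matrix = doc_matrix.matrix if hasattr(doc_matrix, "matrix") else doc_matrix
    return cnn.forward(matrix, train=(mode == "train"), rng=rng)


def default_config(n_stages: int = 5, n_fc: int = 3, n_kernels: int = 8,
                   h: int = 2, k: int = 1, fc_width: int = 64,
                   out_dim: int = 32, dropout_rate: float = 0.5) -> CNNConfig:
    """Build the default-depth configuration (5 conv+pool stages, 3 FC)."""
    stages = [{"h": h, "n_kernels": n_kernels, "k": k} for _ in range(n_stages)]
    fc_sizes = [fc_width] * (n_fc - 1) + [out_dim]
    return CNNConfig(stages=stages, fc_sizes=fc_sizes, dropout_rate=dropout_rate)
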