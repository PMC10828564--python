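"""Minimal feed-forward network engine for the Siamese embedders.

Layers operate on numpy arrays with explicit forward/backward passes and an
Adam optimizer. Images flow channel-last as (batch, H, W, C); dense layers
take (batch, features). Only what the embedding networks need is
implemented: valid-mode single-stage convolution, overlapping max-pooling,
dense layers, ReLU/tanh, inverted dropout.

Gradient correctness is pinned by finite-difference tests rather than by an
autodiff framework.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Tanh",
    "Dropout",
    "Flatten",
    "Network",
    "Adam",
    "build_network",
]


class Layer:
    """Base layer: stateless unless it owns parameters."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: str = "he") -> None:
        super().__init__()
        std = np.sqrt(2.0 / n_in) if scale == "he" else np.sqrt(1.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


class Conv2D(Layer):
    """Valid-mode 2D convolution (cross-correlation), channel-last."""

    def __init__(self, in_channels: int, n_filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = in_channels * kernel * kernel
        self.kernel = kernel
        self.in_channels = in_channels
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, n_filters)),
            "b": np.zeros(n_filters),
        }
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def forward(self, x, train=False):
        if x.ndim == 3:  # single channel images
            x = x[..., None]
        k = self.kernel
        b, h, w, c = x.shape
        windows = sliding_window_view(x, (k, k), axis=(1, 2))  # (B,H',W',C,k,k)
        cols = windows.reshape(b, h - k + 1, w - k + 1, c * k * k)
        self._cols = cols
        self._x_shape = x.shape
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        b, hp, wp, f = grad.shape
        k = self.kernel
        cols2d = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads = {
            "W": cols2d.T @ grad.reshape(-1, f),
            "b": grad.reshape(-1, f).sum(axis=0),
        }
        gcols = (grad @ self.params["W"].T).reshape(
            b, hp, wp, self.in_channels, k, k
        )
        gx = np.zeros(self._x_shape)
        for di in range(k):
            for dj in range(k):
                gx[:, di:di + hp, dj:dj + wp, :] += gcols[:, :, :, :, di, dj]
        return gx


class MaxPool2D(Layer):
    """Max pooling with arbitrary (possibly overlapping) stride."""

    def __init__(self, pool: int = 2, stride: int = 1) -> None:
        super().__init__()
        self.pool = pool
        self.stride = stride
        self._argmax: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def forward(self, x, train=False):
        p, s = self.pool, self.stride
        windows = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::s, ::s]
        flat = windows.reshape(*windows.shape[:4], p * p)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        p, s = self.pool, self.stride
        _, ho, wo, _ = grad.shape
        gx = np.zeros(self._x_shape)
        for t in range(p * p):
            di, dj = divmod(t, p)
            contrib = grad * (self._argmax == t)
            gx[:, di:di + s * ho:s, dj:dj + s * wo:s, :] += contrib
        return gx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Network:
    """A sequential stack with shared weights across Siamese branches.

    There is a single parameter set; both (all) branch inputs are pushed
    through the same instance, which is exactly weight sharing.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pairs = self.parameters()
        if len(weights) != len(pairs):
            raise ValueError("weight list does not match network")
        for (layer, name), w in zip(pairs, weights):
            layer.params[name] = w.copy()


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in network.parameters()]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in network.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.network.parameters()):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_network(
    architecture: str,
    resolution: int,
    dim: int,
    *,
    n_filters: int = 32,
    kernel: int = 5,
    pool: int = 2,
    pool_stride: int = 1,
    hidden: int = 512,
    dropout: float = 0.2,
    seed: int = 0,
) -> Network:
    """Assemble an embedding network.

    cnn: conv(kernel x kernel, n_filters, ReLU) -> max-pool (overlapping,
    stride pool_stride, no padding) -> flatten -> dense hidden ReLU with
    dropout -> dense dim with tanh (embeddings in [-1, 1]^dim).

    fcn: flatten -> dense hidden ReLU with dropout -> dense dim with ReLU.
    """
    rng = np.random.default_rng(seed)
    if architecture == "fcn":
        layers: list[Layer] = [
            Flatten(),
            Dense(resolution * resolution, hidden, rng),
            ReLU(),
            Dropout(dropout, rng),
            Dense(hidden, dim, rng),
            ReLU(),
        ]
    elif architecture == "cnn":
        conv_out = resolution - kernel + 1
        pool_out = (conv_out - pool) // pool_stride + 1
        if pool_out < 1:
            raise ValueError("resolution too small for kernel/pool configuration")
        layers = [
            Conv2D(1, n_filters, kernel, rng),
            ReLU(),
            MaxPool2D(pool, pool_stride),
            Flatten(),
            Dense(pool_out * pool_out * n_filters, hidden, rng),
            ReLU(),
            Dropout(dropout, rng),
            Dense(hidden, dim, rng, scale="glorot"),
            Tanh(),
        ]
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    return Network(layers)
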