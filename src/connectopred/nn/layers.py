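"""Minimal CNN layer kit with explicit forward/backward passes.

All layers operate on float32 NumPy arrays; convolutions are 3x3,
stride 1, same-padding (the only kind used anywhere in the package) and
are evaluated as a single GEMM per layer via an im2col buffer.  Gradient
correctness is established by numeric finite-difference checks in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Flatten",
    "Dense",
    "BatchNorm1D",
    "Dropout",
]

DTYPE = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    """Base layer.

    ``forward(x, train, cache)``: ``train`` selects training-time behaviour
    (batch statistics, dropout); ``cache`` retains the intermediates needed
    by ``backward`` and defaults to ``train``.  Grad-CAM runs an
    inference-mode forward with ``cache=True`` to backpropagate a target
    gradient without perturbing batch-norm or applying dropout.
    """

    params: tuple[Param, ...] = ()
    #: gradient w.r.t. this layer's output, recorded during backward()
    #: (used by Grad-CAM to read activations/gradients at inner layers)
    grad_wrt_output: np.ndarray | None = None
    #: last forward output (only retained by layers that need it anyway)
    last_output: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (C*9, N*H*W) patch matrix for a 3x3 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    col = np.empty((c, 9, n, h * w), dtype=x.dtype)
    for k in range(9):
        di, dj = divmod(k, 3)
        patch = xp[:, :, di : di + h, dj : dj + w]  # (N, C, H, W)
        col[:, k] = patch.transpose(1, 0, 2, 3).reshape(c, n, h * w)
    return col.reshape(c * 9, n * h * w)


def _col2im(dcol: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcol.dtype)
    dcol = dcol.reshape(c, 9, n, h, w)
    for k in range(9):
        di, dj = divmod(k, 3)
        dxp[:, :, di : di + h, dj : dj + w] += dcol[:, k].transpose(1, 0, 2, 3)
    return dxp[:, :, 1:-1, 1:-1]


class Conv2D(Layer):
    """3x3 same-padding convolution, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 name: str = "conv"):
        fan_in = in_channels * 9
        w = rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias")
        self.params = (self.weight, self.bias)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._x_shape: tuple[int, int, int, int] | None = None
        self._col: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col(x)
        out = self.weight.value @ col  # (F, N*H*W)
        out += self.bias.value[:, None]
        self._x_shape = x.shape
        self._col = col if (train if cache is None else cache) else None
        return np.ascontiguousarray(
            out.reshape(self.out_channels, n, h, w).transpose(1, 0, 2, 3)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._col is not None, "backward() requires a cached forward"
        n, c, h, w = self._x_shape
        g = grad.transpose(1, 0, 2, 3).reshape(self.out_channels, n * h * w)
        self.weight.grad += g @ self._col.T
        self.bias.grad += g.sum(axis=1)
        dcol = self.weight.value.T @ g
        return _col2im(dcol, self._x_shape)


class MaxPool2D(Layer):
    """s x s max pooling with stride s (floor division of the spatial size)."""

    def __init__(self, size: int = 2):
        self.size = size
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        s = self.size
        n, c, h, w = x.shape
        h2, w2 = h // s, w // s
        xr = x[:, :, : h2 * s, : w2 * s].reshape(n, c, h2, s, w2, s)
        xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, s * s)
        idx = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx) if (train if cache is None else cache) else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, c, h, w), idx = self._cache
        s = self.size
        h2, w2 = h // s, w // s
        dxf = np.zeros((n, c, h2, w2, s * s), dtype=grad.dtype)
        np.put_along_axis(dxf, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, : h2 * s, : w2 * s] = (
            dxf.reshape(n, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * s, w2 * s)
        )
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = x > 0 if (train if cache is None else cache) else None
        self.last_output = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 name: str = "dense"):
        w = rng.standard_normal((in_features, out_features)) * np.sqrt(2.0 / in_features)
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias")
        self.params = (self.weight, self.bias)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        self._x = x if (train if cache is None else cache) else None
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class BatchNorm1D(Layer):
    """Batch normalization over feature vectors (training-mode batch stats,
    exponential running stats for inference)."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(dim), f"{name}.gamma")
        self.beta = Param(np.zeros(dim), f"{name}.beta")
        self.params = (self.gamma, self.beta)
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_sd
        self._cache = (xhat, inv_sd, train) if (train if cache is None else cache) else None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd, trained = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        gh = grad * self.gamma.value
        if not trained:
            # inference mode: mu/var are constants, BN is a fixed affine map
            return gh * inv_sd
        n = grad.shape[0]
        return inv_sd / n * (
            n * gh - gh.sum(axis=0) - xhat * (gh * xhat).sum(axis=0)
        )


class Dropout(Layer):
    """Inverted dropout; the training loop injects the RNG for determinism."""

    def __init__(self, rate: float = 0.5):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert self.rng is not None, "Dropout needs an RNG in training mode"
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._mask = self._mask.astype(x.dtype)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask
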