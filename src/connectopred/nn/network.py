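"""Sequential container and Adam optimizer for the layer kit."""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np

from .layers import DTYPE, Dropout, Layer, Param

__all__ = ["Sequential", "Adam", "checksum_params"]


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    @property
    def params(self) -> tuple[Param, ...]:
        return tuple(p for layer in self.layers for p in layer.params)

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train=train, cache=cache)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Backpropagate, recording each layer's output gradient on the way."""
        for layer in reversed(self.layers):
            layer.grad_wrt_output = grad
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self.params)}
        # batch-norm running statistics are state, not parameters
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                state[f"rm{i}"] = layer.running_mean.copy()
                state[f"rv{i}"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.value[...] = state[f"p{i}"]
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                layer.running_mean = state[f"rm{i}"].copy()
                layer.running_var = state[f"rv{i}"].copy()


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: Iterable[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = tuple(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def checksum_params(arrays: Iterable[np.ndarray]) -> str:
    """SHA-256 over the raw bytes of a sequence of arrays."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()
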