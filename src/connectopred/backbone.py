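"""Frozen very-deep convolutional feature extractor (VGG19-style).

The backbone is the convolution/pooling stack of VGG19: 16 convolutional
layers (3x3 kernels, ReLU) with channel widths
64,64,128,128,256,256,256,256,512x8 and five 2x2/stride-2 max-pool stages
after layers 2, 4, 8, 12 and 16.  On a 90x90 input the spatial size
shrinks 90 -> 45 -> 22 -> 11 -> 5 -> 2, so the output feature map is
2x2x512.

Weights come either from an external pretrained-weights file (``.npz``
with arrays ``conv{i}_weight``/``conv{i}_bias``) or from a deterministic
He-normal random initialization of the same architecture.  In either case
the backbone is frozen: its parameters are excluded from every gradient
update, which also makes its features a pure function of the input —
exploited by an internal content-addressed feature cache so that repeated
cross-validation never recomputes features for the same connectome.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atlas import N_REGIONS
from .connectome import Connectome
from .nn.layers import DTYPE, _im2col
from .nn.network import checksum_params

__all__ = ["BackboneSpec", "FrozenBackbone", "build_backbone", "adapt_input"]

VGG19_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 256,
                512, 512, 512, 512, 512, 512, 512, 512)
POOL_AFTER = frozenset({2, 4, 8, 12, 16})
FEATURE_SHAPE = (512, 2, 2)
_CHUNK = 8  # images per im2col buffer (bounds peak memory)


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture + weight provenance of the frozen feature extractor."""

    widths: tuple[int, ...] = VGG19_WIDTHS
    pool_after: frozenset[int] = POOL_AFTER
    weights_file: str | None = None
    init_seed: int = 0
    frozen: bool = True

    def __post_init__(self) -> None:
        if len(self.widths) != 16:
            raise ValueError("backbone must have exactly 16 convolutional layers")


def adapt_input(c: Connectome | np.ndarray, mode: str = "standardize") -> np.ndarray:
    """Map a 90x90 connectome to a 3-channel backbone input tensor.

    The matrix is replicated onto all three channels (the backbone is a
    colour-image architecture; a connectome has one channel).  ``mode``:

    - ``"standardize"`` (default, used with random-init weights): each
      matrix is shifted/scaled to zero mean and unit variance over its own
      entries.  Per-matrix standardization is leakage-free and keeps the
      mapping a pure function of the matrix (a requirement of the feature
      cache).
    - ``"unit"``: values kept on the raw [0, 1] FA scale (for externally
      pretrained weight files that expect bounded inputs).
    """
    m = c.matrix if isinstance(c, Connectome) else np.asarray(c)
    if m.shape != (N_REGIONS, N_REGIONS):
        raise ValueError(f"expected a {N_REGIONS}x{N_REGIONS} matrix, got {m.shape}")
    x = m.astype(DTYPE)
    if mode == "standardize":
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    elif mode != "unit":
        raise ValueError(f"unknown input mode {mode!r}")
    return np.repeat(x[None], 3, axis=0)


class FrozenBackbone:
    """Frozen conv/pool stack mapping (n, 3, 90, 90) -> (n, 512, 2, 2)."""

    def __init__(self, spec: BackboneSpec = BackboneSpec()):
        self.spec = spec
        self.input_mode = "standardize" if spec.weights_file is None else "unit"
        if spec.weights_file is not None:
            self.weights, self.biases = self._load_weights(spec)
        else:
            self.weights, self.biases = self._random_weights(spec)
        for w, b in zip(self.weights, self.biases):
            w.setflags(write=False)
            b.setflags(write=False)
        self._cache: dict[bytes, np.ndarray] = {}

    @staticmethod
    def _random_weights(spec: BackboneSpec):
        rng = np.random.default_rng(spec.init_seed)
        weights, biases = [], []
        c = 3
        for f in spec.widths:
            fan_in = c * 9
            weights.append(
                (rng.standard_normal((f, fan_in)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
            )
            biases.append(np.zeros(f, dtype=DTYPE))
            c = f
        return weights, biases

    @staticmethod
    def _load_weights(spec: BackboneSpec):
        path = Path(spec.weights_file)
        if not path.exists():
            raise FileNotFoundError(f"backbone weights file not found: {path}")
        data = np.load(path)
        weights, biases = [], []
        c = 3
        for i, f in enumerate(spec.widths):
            try:
                w = np.asarray(data[f"conv{i}_weight"], dtype=DTYPE)
                b = np.asarray(data[f"conv{i}_bias"], dtype=DTYPE)
            except KeyError as exc:
                raise ValueError(f"{path}: missing array for conv layer {i}") from exc
            if w.shape == (f, c, 3, 3):
                w = w.reshape(f, c * 9)
            if w.shape != (f, c * 9) or b.shape != (f,):
                raise ValueError(
                    f"{path}: conv{i} weight shape {w.shape} incompatible with "
                    f"{f} filters on {c} input channels"
                )
            weights.append(w)
            biases.append(b)
            c = f
        return weights, biases

    @property
    def n_conv_layers(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return int(np.prod(FEATURE_SHAPE))

    def checksum(self) -> str:
        """Fingerprint of all backbone parameters (frozen-contract audits)."""
        return checksum_params([*self.weights, *self.biases])

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Run the conv/pool stack; input (n, 3, H, W), float32."""
        out = []
        for i0 in range(0, x.shape[0], _CHUNK):
            out.append(self._forward_chunk(np.ascontiguousarray(x[i0 : i0 + _CHUNK],
                                                                dtype=DTYPE)))
        return np.concatenate(out) if len(out) > 1 else out[0]

    def _forward_chunk(self, x: np.ndarray) -> np.ndarray:
        for i, (w, b) in enumerate(zip(self.weights, self.biases), start=1):
            n, c, h, wd = x.shape
            col = _im2col(x)
            z = w @ col
            z += b[:, None]
            x = np.maximum(
                z.reshape(w.shape[0], n, h, wd).transpose(1, 0, 2, 3), 0.0
            )
            if i in self.spec.pool_after:
                h2, w2 = h // 2, wd // 2
                x = x[:, :, : h2 * 2, : w2 * 2].reshape(n, x.shape[1], h2, 2, w2, 2)
                x = x.max(axis=(3, 5))
        return np.ascontiguousarray(x)

    def features(self, matrices: np.ndarray) -> np.ndarray:
        """Features for a stack of (n, 90, 90) connectome matrices, cached.

        The cache key is the raw content of each matrix, so identical
        subjects appearing in different folds/repeats cost one forward
        pass in total.
        """
        matrices = np.asarray(matrices)
        if matrices.ndim == 2:
            matrices = matrices[None]
        keys = [np.ascontiguousarray(m, dtype=DTYPE).tobytes() for m in matrices]
        missing = [i for i, k in enumerate(keys) if k not in self._cache]
        if missing:
            batch = np.stack(
                [adapt_input(matrices[i], self.input_mode) for i in missing]
            )
            feats = self.forward(batch)
            for i, f in zip(missing, feats):
                self._cache[keys[i]] = f
        return np.stack([self._cache[k] for k in keys])

    def clear_cache(self) -> None:
        self._cache.clear()


def build_backbone(spec: BackboneSpec = BackboneSpec()) -> FrozenBackbone:
    """Construct the frozen feature extractor described by ``spec``."""
    return FrozenBackbone(spec)
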