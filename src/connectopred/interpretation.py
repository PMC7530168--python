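"""Grad-CAM edge importance on the connectome adjacency matrix.

For a trained TL-CNN, the class-activation map is computed at the last
convolutional layer of the network (the second head convolution): each
channel is weighted by the spatial mean of the target-output gradient
over its activation map, the weighted sum is rectified (ReLU), bilinearly
upsampled to 90x90, symmetrized and zero-diagonalized, yielding a
nonnegative edge-saliency matrix.  Per-subject maps are min-max
normalized and averaged into a cohort-level importance map, whose
strongest upper-triangle entries give the top-k discriminative
region-pair ranking with anatomical names from the atlas.

Note the intrinsic coarseness: the head convolutions operate on the
2x2x512 backbone output, so a single map has 2x2 spatial degrees of
freedom before upsampling ("a coarse localization map").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .atlas import N_REGIONS, AtlasDefinition
from .connectome import Cohort, Subject
from .models import FittedTLCNN

__all__ = [
    "ImportanceMap",
    "EdgeRanking",
    "RankedEdge",
    "gradcam",
    "gradcam_maps",
    "aggregate_importance",
    "rank_edges",
    "edge_outcome_correlation",
    "UnsupportedModelError",
]


class UnsupportedModelError(TypeError):
    """Saliency requested from a model without convolutional activations."""


@dataclass(frozen=True)
class ImportanceMap:
    """Symmetric nonnegative 90x90 saliency matrix with zero diagonal."""

    matrix: np.ndarray
    atlas: AtlasDefinition

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_REGIONS, N_REGIONS):
            raise ValueError(f"importance map must be 90x90, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("importance map must be symmetric")
        if m.min() < 0:
            raise ValueError("importance map must be nonnegative")
        if np.abs(np.diag(m)).max() > 0:
            raise ValueError("importance map must have a zero diagonal")
        m = (m + m.T) / 2
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def normalized(self) -> "ImportanceMap":
        """Min-max normalization of off-diagonal entries to [0, 1]."""
        m = self.matrix.copy()
        off = ~np.eye(N_REGIONS, dtype=bool)
        lo, hi = m[off].min(), m[off].max()
        if hi > lo:
            m[off] = (m[off] - lo) / (hi - lo)
        elif hi > 0:
            m[off] = 1.0
        np.fill_diagonal(m, 0.0)
        return ImportanceMap(m, self.atlas)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.matrix, cmap="magma")
        ax.set_xlabel("region index")
        ax.set_ylabel("region index")
        plt.colorbar(im, ax=ax, label="importance")
        return ax


class RankedEdge(NamedTuple):
    region_a: str
    abbrev_a: str
    region_b: str
    abbrev_b: str
    importance: float
    outcome_r: float | None = None


@dataclass(frozen=True)
class EdgeRanking:
    """Top-k edges by importance, non-increasing, ties broken by index."""

    edges: tuple[RankedEdge, ...]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def __getitem__(self, i):
        return self.edges[i]

    def to_tsv(self) -> str:
        lines = ["region_a\tabbrev_a\tregion_b\tabbrev_b\timportance\toutcome_r"]
        for e in self.edges:
            r = "" if e.outcome_r is None else (
                "NA" if np.isnan(e.outcome_r) else f"{e.outcome_r:.4f}")
            lines.append(
                f"{e.region_a}\t{e.abbrev_a}\t{e.region_b}\t{e.abbrev_b}\t"
                f"{e.importance:.6f}\t{r}"
            )
        return "\n".join(lines) + "\n"


def _bilinear_resize(a: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling with pixel-center alignment (edge padding)."""
    in_h, in_w = a.shape
    out_h, out_w = out_shape

    def coords(n_out, n_in):
        c = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        return np.clip(c, 0, n_in - 1)

    ys, xs = coords(out_h, in_h), coords(out_w, in_w)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, in_h - 1)
    x1 = np.minimum(x0 + 1, in_w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    return (
        a[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + a[np.ix_(y0, x1)] * (1 - wy) * wx
        + a[np.ix_(y1, x0)] * wy * (1 - wx)
        + a[np.ix_(y1, x1)] * wy * wx
    )


def gradcam(
    model: FittedTLCNN,
    subject: Subject,
    target: str = "high-risk",
) -> ImportanceMap:
    """Grad-CAM saliency of one subject's connectome under a trained TL-CNN.

    ``target`` is ``"high-risk"`` (the high-risk logit), ``"low-risk"``,
    or ``"regression"`` (the linear output; required and implied for
    regression models).
    """
    if not isinstance(model, FittedTLCNN):
        raise UnsupportedModelError(
            f"Grad-CAM needs convolutional activations; model kind "
            f"{getattr(model, 'kind', type(model).__name__)!r} has none"
        )
    if model.task == "regression":
        target_class = 0
    else:
        target_class = {"high-risk": 1, "low-risk": 0}.get(target)
        if target_class is None:
            raise ValueError(f"unknown target {target!r} for classification")
    feats = model.backbone.features(subject.connectome.matrix[None])
    acts, grads = model.head_forward_with_grad(feats, target_class=target_class)
    a, g = acts[0], grads[0]  # (C, h, w)
    weights = g.mean(axis=(1, 2))  # spatial-mean gradient per channel
    cam = np.maximum(np.tensordot(weights, a, axes=1), 0.0)
    up = _bilinear_resize(cam.astype(np.float64), (N_REGIONS, N_REGIONS))
    up = (up + up.T) / 2
    np.fill_diagonal(up, 0.0)
    return ImportanceMap(up, subject.connectome.atlas)


def gradcam_maps(model: FittedTLCNN, cohort: Cohort,
                 target: str = "high-risk") -> list[ImportanceMap]:
    return [gradcam(model, s, target) for s in cohort]


def aggregate_importance(maps: Sequence[ImportanceMap]) -> ImportanceMap:
    """Entrywise mean of min-max normalized per-subject maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one importance map")
    atlas = maps[0].atlas
    acc = np.zeros((N_REGIONS, N_REGIONS))
    for m in maps:
        acc += m.normalized().matrix
    return ImportanceMap(acc / len(maps), atlas)


def rank_edges(importance: ImportanceMap, atlas: AtlasDefinition | None = None,
               k: int = 15,
               outcome_r: dict[tuple[int, int], float] | None = None
               ) -> EdgeRanking:
    """Top-k upper-triangle edges by importance with deterministic ties.

    Ties are broken lexicographically by (min region index, max region
    index).  ``outcome_r`` optionally attaches per-edge outcome
    correlations keyed by 1-based (i, j) pairs.
    """
    atlas = atlas or importance.atlas
    iu, ju = np.triu_indices(N_REGIONS, k=1)
    if k > len(iu):
        raise ValueError(f"k={k} exceeds the {len(iu)} distinct edges")
    vals = importance.matrix[iu, ju]
    order = np.lexsort((ju, iu, -vals))[:k]
    edges = []
    for o in order:
        i, j = int(iu[o]) + 1, int(ju[o]) + 1
        ra, rb = atlas.region(i), atlas.region(j)
        r = outcome_r.get((i, j)) if outcome_r else None
        edges.append(RankedEdge(ra.name, ra.abbreviation, rb.name,
                                rb.abbreviation, float(vals[o]), r))
    return EdgeRanking(tuple(edges))


def edge_outcome_correlation(
    cohort: Cohort, edges: Iterable[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Pearson r between each edge's FA weight and the cognitive score.

    Zero-variance edges are flagged with NaN rather than failing.
    """
    from scipy import stats

    if len(cohort) < 3:
        raise ValueError("need at least three subjects for edge correlations")
    scores = cohort.scores
    mats = cohort.matrices()
    out: dict[tuple[int, int], float] = {}
    for i, j in edges:
        if not (1 <= i < j <= N_REGIONS):
            raise ValueError(f"edge ({i},{j}) must satisfy 1 <= i < j <= {N_REGIONS}")
        w = mats[:, i - 1, j - 1]
        if np.std(w) == 0 or np.std(scores) == 0:
            out[(i, j)] = float("nan")
        else:
            out[(i, j)] = float(stats.pearsonr(w, scores)[0])
    return out


def edge_ranks(importance: ImportanceMap,
               edges: Iterable[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """1-based rank (1 = most important) of given edges in the full ranking."""
    iu, ju = np.triu_indices(N_REGIONS, k=1)
    vals = importance.matrix[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    rank_of_pos = np.empty(len(order), dtype=int)
    rank_of_pos[order] = np.arange(1, len(order) + 1)
    pos_lookup = {(int(a) + 1, int(b) + 1): p for p, (a, b) in enumerate(zip(iu, ju))}
    return {e: int(rank_of_pos[pos_lookup[e]]) for e in edges}
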