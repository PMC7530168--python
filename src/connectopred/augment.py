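"""Score-binned convex-combination oversampling (SMOTE for continuous labels).

Training subjects are divided into five score bins ([40,70), [70,80),
[80,90), [90,100), [100,160]); bins are visited round-robin, a base sample
is drawn uniformly from the visited bin, its k nearest neighbours (k = 5 by
default, Euclidean distance on the 4005-edge vectors) are found, and a
synthetic subject is formed as a convex combination of the k+1 connectomes
with weights drawn uniformly on the simplex.  The synthetic label is the
same convex combination of the contributors' scores.  Sampling repeats
until the training set reaches ``expansion_factor`` times its original
size (originals retained).

Neighbours are searched within the base sample's bin when it holds at
least k+1 members, otherwise over the whole training set.  Bases and
neighbours are always original subjects — synthetic samples never feed
back into the pool — so every synthetic subject carries an exact list of
contributor ids, which the cross-validation driver uses for its leakage
audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import Cohort, Connectome, Subject

__all__ = [
    "AugmentationConfig",
    "SyntheticDraw",
    "assign_bin",
    "synthesize_sample",
    "augment",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class AugmentationConfig:
    bin_edges: tuple[float, ...] = (70.0, 80.0, 90.0, 100.0)
    k: int = 5
    expansion_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("neighbour count k must be >= 1")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if list(self.bin_edges) != sorted(set(self.bin_edges)):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) + 1


def assign_bin(score: float, config: AugmentationConfig | None = None) -> int:
    """Bin index 0..4 for a score; intervals are left-closed ([70,80) etc.)."""
    config = config or AugmentationConfig()
    if not 40.0 <= score <= 160.0:
        raise ValueError(f"score {score} outside the 40-160 scale")
    return int(np.searchsorted(config.bin_edges, score, side="right"))


@dataclass(frozen=True)
class SyntheticDraw:
    """One convex-combination draw: contributors, weights and the result."""

    base: Subject
    neighbors: tuple[Subject, ...]
    weights: np.ndarray
    x_syn: Connectome
    y_syn: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.neighbors) + 1,):
            raise ValueError("need one weight per contributor (base + neighbours)")
        if w.min() < 0 or abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must be nonnegative and sum to 1, got {w}")
        object.__setattr__(self, "weights", w)

    @property
    def contributor_ids(self) -> tuple[str, ...]:
        return (self.base.id, *(s.id for s in self.neighbors))


def synthesize_sample(
    base: Subject, neighbors: Sequence[Subject], weights: Sequence[float]
) -> SyntheticDraw:
    """Convex combination of base + neighbours, applied to matrices and scores."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] != len(neighbors) + 1:
        raise ValueError("need one weight per contributor (base + neighbours)")
    if w.min() < 0 or abs(w.sum() - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"weights must be nonnegative and sum to 1, got {w}")
    contributors = (base, *neighbors)
    mats = np.stack([s.connectome.matrix for s in contributors])
    x = np.einsum("m,mij->ij", w, mats)
    x = (x + x.T) / 2
    np.fill_diagonal(x, 0.0)
    y = float(w @ np.array([s.score for s in contributors]))
    return SyntheticDraw(
        base=base,
        neighbors=tuple(neighbors),
        weights=w,
        x_syn=Connectome(x, base.connectome.atlas),
        y_syn=y,
    )


def _nearest_neighbors(
    edge_matrix: np.ndarray, pool: np.ndarray, base_idx: int, k: int
) -> np.ndarray:
    """Indices (into the cohort) of the k pool members closest to base_idx."""
    candidates = pool[pool != base_idx]
    d = np.linalg.norm(edge_matrix[candidates] - edge_matrix[base_idx], axis=1)
    order = np.argsort(d, kind="stable")  # index order breaks distance ties
    return candidates[order[:k]]


def augment(training: Cohort, config: AugmentationConfig) -> Cohort:
    """Expand a training cohort to ``round(expansion_factor * n)`` subjects.

    Deterministic for equal (cohort, config): all randomness comes from
    ``config.seed``.
    """
    n = len(training)
    if n < config.k + 1:
        raise ValueError(
            f"augmentation needs at least k+1={config.k + 1} subjects, got {n}"
        )
    total = int(round(config.expansion_factor * n))
    n_syn = total - n
    if n_syn <= 0:
        return training

    rng = np.random.default_rng(config.seed)
    edge_matrix = training.edge_matrix()
    bins = [[] for _ in range(config.n_bins)]
    for idx, s in enumerate(training):
        bins[assign_bin(s.score, config)].append(idx)
    bins = [np.array(b, dtype=int) for b in bins]
    all_idx = np.arange(n)

    synthetic: list[Subject] = []
    bin_cursor = 0
    while len(synthetic) < n_syn:
        b = bin_cursor % config.n_bins
        bin_cursor += 1
        members = bins[b]
        if len(members) == 0:
            continue  # empty bins are skipped in the round-robin
        base_idx = int(rng.choice(members))
        pool = members if len(members) >= config.k + 1 else all_idx
        nn = _nearest_neighbors(edge_matrix, pool, base_idx, config.k)
        weights = rng.dirichlet(np.ones(len(nn) + 1))
        draw = synthesize_sample(
            training[base_idx], [training[int(i)] for i in nn], weights
        )
        sid = f"syn{len(synthetic) + 1:05d}"
        synthetic.append(
            Subject(
                sid,
                draw.x_syn,
                draw.y_syn,
                contributors=draw.contributor_ids,
            )
        )
    return Cohort((*training.subjects, *synthetic), provenance="augmented")
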