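"""Synthetic cohort generator with planted score-correlated edges.

The generator emulates the statistical skeleton of a very-preterm outcome
cohort: Bayley-III-style cognitive scores drawn from Normal(100, 15) and
clamped to the 40-160 scale (so about 25% of subjects fall in the
score < 90 high-risk class), and symmetric FA-weighted 90x90 connectomes
in which a chosen set of "effect" edges varies linearly with the
standardized score while all remaining edges are pure noise around a
baseline FA pattern.

The linear effect model for a planted edge (i, j, alpha) is

    w_ij = baseline_ij + alpha * scale * z + eps,   z = (score - mean)/sd

with ``scale`` = 0.1 FA units per score SD by default, i.e. |alpha| is the
fraction of that full effect.  Scores are clamped *before* z is computed so
that the stored score, the risk label and the planted effect always agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas import N_REGIONS, AtlasDefinition, load_atlas
from .connectome import Cohort, Connectome, Subject

__all__ = ["GeneratorConfig", "generate_cohort", "generate_source_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Effect edges are (i, j, alpha) with 1-based atlas region indices i < j
    and a signed effect strength alpha in [-1, 1].
    """

    n: int = 80
    effect_edges: tuple[tuple[int, int, float], ...] = ()
    baseline_fa: float | np.ndarray = 0.4
    edge_noise_sd: float = 0.02
    effect_scale: float = 0.1  # FA units per score SD at |alpha| = 1
    score_mean: float = 100.0
    score_sd: float = 15.0
    score_bounds: tuple[float, float] = (40.0, 160.0)
    fa_bounds: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.edge_noise_sd < 0:
            raise ValueError("edge_noise_sd must be >= 0")
        for i, j, alpha in self.effect_edges:
            if i == j:
                raise ValueError(f"effect edge ({i},{j}) lies on the diagonal")
            if not (1 <= i < j <= N_REGIONS):
                raise ValueError(
                    f"effect edge ({i},{j}) must satisfy 1 <= i < j <= {N_REGIONS}"
                )
            if not -1.0 <= alpha <= 1.0:
                raise ValueError(f"effect strength alpha={alpha} outside [-1, 1]")

    def baseline_matrix(self) -> np.ndarray:
        """Off-diagonal baseline FA pattern as a (90, 90) array."""
        if np.isscalar(self.baseline_fa):
            base = np.full((N_REGIONS, N_REGIONS), float(self.baseline_fa))
        else:
            base = np.asarray(self.baseline_fa, dtype=float).copy()
            if base.shape != (N_REGIONS, N_REGIONS):
                raise ValueError("baseline matrix must be 90x90")
            base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
        return base


def generate_cohort(
    config: GeneratorConfig,
    atlas: AtlasDefinition | None = None,
    id_prefix: str = "S",
) -> Cohort:
    """Draw a synthetic cohort; byte-reproducible from ``config.seed``."""
    atlas = atlas or load_atlas()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.score_bounds
    scores = np.clip(rng.normal(config.score_mean, config.score_sd, config.n), lo, hi)
    z = (scores - config.score_mean) / config.score_sd
    base = config.baseline_matrix()
    triu = np.triu_indices(N_REGIONS, k=1)
    effect_pos = {}
    for i, j, alpha in config.effect_edges:
        effect_pos[(i - 1, j - 1)] = alpha

    subjects = []
    width = max(4, len(str(config.n)))
    for s in range(config.n):
        noise = rng.normal(0.0, config.edge_noise_sd, size=len(triu[0]))
        m = base.copy()
        m[triu] += noise
        for (a, b), alpha in effect_pos.items():
            m[a, b] = base[a, b] + alpha * config.effect_scale * z[s] + rng.normal(
                0.0, config.edge_noise_sd
            )
        np.clip(m, *config.fa_bounds, out=m)
        m = np.triu(m, k=1)
        m = m + m.T
        subjects.append(
            Subject(f"{id_prefix}{s + 1:0{width}d}", Connectome(m, atlas), float(scores[s]))
        )
    return Cohort(tuple(subjects), provenance="synthetic")


def generate_source_cohort(
    n: int, seed: int, atlas: AtlasDefinition | None = None
) -> Cohort:
    """Unlabelled source-domain pool for unsupervised pretraining.

    Mimics a pool of full-term neonatal connectomes: same matrix geometry
    as the target generator but with a shifted baseline FA (a
    distribution-level domain gap).  Scores are drawn for completeness but
    flagged unused.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = GeneratorConfig(n=n, baseline_fa=0.45, edge_noise_sd=0.03, seed=seed)
    cohort = generate_cohort(config, atlas=atlas, id_prefix="SRC")
    return Cohort(cohort.subjects, provenance="synthetic", scores_unused=True)
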