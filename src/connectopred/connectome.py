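"""Connectome containers, file I/O, edge vectorization and risk labelling.

A connectome is a 90x90 symmetric adjacency matrix of mean-FA edge weights
in [0, 1] with a zero diagonal.  Edge vectorization uses a single fixed
convention throughout the package: upper triangle, row-major, i < j,
0-based positions, giving vectors of length 90*89/2 = 4005.

Cognitive scores follow the Bayley-III convention (scale 40-160, population
mean 100, SD 15); a score below 90 defines the high-risk class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .atlas import N_REGIONS, AtlasDefinition, load_atlas

__all__ = [
    "Connectome",
    "EdgeVector",
    "Subject",
    "Cohort",
    "ConnectomeFormatError",
    "N_EDGES",
    "SCORE_RANGE",
    "RISK_THRESHOLD",
    "assign_risk_label",
    "read_connectome",
    "write_connectome",
    "vectorize_edges",
    "devectorize_edges",
    "read_manifest",
    "write_manifest",
]

N_EDGES = N_REGIONS * (N_REGIONS - 1) // 2  # 4005
SCORE_RANGE = (40.0, 160.0)
RISK_THRESHOLD = 90.0
SYMMETRY_TOL = 1e-9

RiskLabel = Literal["high", "low"]
_TRIU = np.triu_indices(N_REGIONS, k=1)  # row-major over i<j


class ConnectomeFormatError(ValueError):
    """Raised for malformed connectome files or invalid matrices."""


def assign_risk_label(score: float) -> RiskLabel:
    """Dichotomize a cognitive score: ``high`` risk iff score < 90."""
    if not SCORE_RANGE[0] <= score <= SCORE_RANGE[1]:
        raise ValueError(f"score {score} outside the {SCORE_RANGE} scale")
    return "high" if score < RISK_THRESHOLD else "low"


@dataclass(frozen=True)
class Connectome:
    """Validated FA-weighted adjacency matrix bound to an atlas."""

    matrix: np.ndarray
    atlas: AtlasDefinition

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_REGIONS, N_REGIONS):
            raise ConnectomeFormatError(
                f"connectome matrix must be {N_REGIONS}x{N_REGIONS}, got {m.shape}"
            )
        asym = np.abs(m - m.T)
        if asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ConnectomeFormatError(
                f"matrix asymmetric at ({i + 1},{j + 1}): "
                f"{m[i, j]!r} vs {m[j, i]!r} (tol {SYMMETRY_TOL})"
            )
        m = (m + m.T) / 2.0  # absorb round-trip float noise
        if np.diag(m).any():
            i = int(np.flatnonzero(np.diag(m))[0])
            raise ConnectomeFormatError(f"nonzero diagonal entry at ({i + 1},{i + 1})")
        if m.min() < 0.0 or m.max() > 1.0:
            i, j = np.unravel_index(np.argmax(np.abs(m - 0.5)), m.shape)
            raise ConnectomeFormatError(
                f"FA weight outside [0,1] at ({i + 1},{j + 1}): {m[i, j]!r}"
            )
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def edge(self, i: int, j: int) -> float:
        """Weight of edge between 1-based region indices i and j."""
        return float(self.matrix[i - 1, j - 1])


@dataclass(frozen=True)
class EdgeVector:
    """Length-4005 upper-triangle edge vector (row-major, i<j, 0-based)."""

    values: np.ndarray
    atlas: AtlasDefinition

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_EDGES,):
            raise ValueError(f"edge vector must have length {N_EDGES}, got {v.shape}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def vectorize_edges(c: Connectome) -> EdgeVector:
    return EdgeVector(c.matrix[_TRIU].copy(), c.atlas)


def devectorize_edges(v: EdgeVector) -> Connectome:
    m = np.zeros((N_REGIONS, N_REGIONS))
    m[_TRIU] = v.values
    m += m.T
    return Connectome(m, v.atlas)


def edge_position(i: int, j: int) -> int:
    """0-based position of edge (i, j), 1-based region indices, in the vector."""
    if not (1 <= i < j <= N_REGIONS):
        raise ValueError(f"edge ({i},{j}) must satisfy 1 <= i < j <= {N_REGIONS}")
    a, b = i - 1, j - 1
    return a * N_REGIONS - a * (a + 1) // 2 + (b - a - 1)


@dataclass(frozen=True)
class Subject:
    id: str
    connectome: Connectome
    score: float
    risk_label: RiskLabel = field(init=False)
    contributors: tuple[str, ...] = ()
    """Ids of the original subjects a synthetic sample was mixed from."""

    def __post_init__(self) -> None:
        object.__setattr__(self, "risk_label", assign_risk_label(self.score))


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of subjects sharing one atlas."""

    subjects: tuple[Subject, ...]
    provenance: Literal["real", "synthetic", "augmented"] = "real"
    scores_unused: bool = False
    """True for source-domain pools whose scores are placeholders."""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        atlases = {id(s.connectome.atlas) for s in self.subjects}
        if len(atlases) > 1:
            abbrs = {s.connectome.atlas.abbreviations for s in self.subjects}
            if len(abbrs) > 1:
                raise ValueError("all subjects in a cohort must share one atlas")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> Subject:
        return self.subjects[i]

    @property
    def atlas(self) -> AtlasDefinition:
        return self.subjects[0].connectome.atlas

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.subjects)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.subjects])

    @property
    def labels(self) -> np.ndarray:
        """Binary risk labels: 1 = high risk (score < 90)."""
        return np.array([1 if s.risk_label == "high" else 0 for s in self.subjects])

    def matrices(self, dtype=np.float64) -> np.ndarray:
        """Stacked (n, 90, 90) adjacency matrices."""
        return np.stack([s.connectome.matrix for s in self.subjects]).astype(dtype)

    def edge_matrix(self) -> np.ndarray:
        """(n, 4005) matrix of edge vectors."""
        return np.stack([s.connectome.matrix[_TRIU] for s in self.subjects])

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return replace(self, subjects=tuple(self.subjects[int(i)] for i in indices))


# ---------------------------------------------------------------------------
# file formats: connectome CSV and cohort manifest TSV
# ---------------------------------------------------------------------------

def read_connectome(path: str | Path, atlas: AtlasDefinition) -> Connectome:
    """Read a 90x90 connectome CSV (optional header row/column of abbreviations)."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise ConnectomeFormatError(f"{path}: empty file")

    def _is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    if not _is_number(rows[0][-1]):
        rows = rows[1:]  # header row
    has_label_col = bool(rows) and not _is_number(rows[0][0])
    data = []
    for r, row in enumerate(rows):
        cells = row[1:] if has_label_col else row
        vals = []
        for c, cell in enumerate(cells):
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise ConnectomeFormatError(
                    f"{path}: non-numeric cell at row {r + 1}, column {c + 1}: {cell!r}"
                ) from exc
        data.append(vals)
    m = np.array(data, dtype=float)
    if m.shape != (N_REGIONS, N_REGIONS):
        raise ConnectomeFormatError(
            f"{path}: expected a {N_REGIONS}x{N_REGIONS} table, got {m.shape}"
        )
    try:
        return Connectome(m, atlas)
    except ConnectomeFormatError as exc:
        raise ConnectomeFormatError(f"{path}: {exc}") from exc


def write_connectome(c: Connectome, path: str | Path) -> None:
    """Write a connectome CSV with abbreviation headers (round-trip exact)."""
    path = Path(path)
    abbrevs = c.atlas.abbreviations
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region", *abbrevs])
        for i, row in enumerate(c.matrix):
            w.writerow([abbrevs[i], *(repr(float(x)) for x in row)])


def write_manifest(cohort: Cohort, directory: str | Path, stem: str = "cohort") -> Path:
    """Write per-subject connectome CSVs plus a TSV manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / f"{stem}.tsv"
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "connectome_path", "score"])
        for s in cohort:
            rel = f"{stem}_{s.id}.csv"
            write_connectome(s.connectome, directory / rel)
            w.writerow([s.id, rel, repr(float(s.score))])
    return manifest


def read_manifest(
    path: str | Path, atlas: AtlasDefinition | None = None, provenance: str = "real"
) -> Cohort:
    """Read a cohort manifest TSV (subject_id, connectome_path, score)."""
    path = Path(path)
    atlas = atlas or load_atlas()
    subjects = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0] == "subject_id":
                continue
            sid, rel, score = row[0], row[1], float(row[2])
            cpath = Path(rel)
            if not cpath.is_absolute():
                cpath = path.parent / cpath
            subjects.append(Subject(sid, read_connectome(cpath, atlas), score))
    return Cohort(tuple(subjects), provenance=provenance)  # type: ignore[arg-type]
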