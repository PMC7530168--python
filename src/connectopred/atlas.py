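"""Neonatal 90-region AAL-style atlas used to label connectome nodes.

The connectome node ordering follows the neonatal automated anatomical
labelling scheme: 90 cerebral regions (no cerebellum), numbered 1-90,
left/right homologues interleaved, with spatially nearby regions carrying
adjacent indices.  Lobe membership is defined on index ranges:

    frontal   1-28, 69-70
    occipital 43-54
    parietal  61-68
    central   55-60
    temporal  37-42, 71-90

Indices 29-36 (insula and cingulate regions) are not covered by that
grouping; they are tagged ``unlisted`` rather than being force-assigned to
an anatomical lobe.  Lobe labels are used for reporting only and play no
role in model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

__all__ = [
    "Region",
    "AtlasDefinition",
    "AtlasError",
    "load_atlas",
    "BUILTIN_ATLAS_TOKEN",
    "N_REGIONS",
]

N_REGIONS = 90
BUILTIN_ATLAS_TOKEN = "neonatal-aal-90"

LOBE_RANGES: Mapping[str, tuple[range, ...]] = {
    "frontal": (range(1, 29), range(69, 71)),
    "occipital": (range(43, 55),),
    "parietal": (range(61, 69),),
    "central": (range(55, 61),),
    "temporal": (range(37, 43), range(71, 91)),
}
UNLISTED_LOBE = "unlisted"


class AtlasError(ValueError):
    """Raised when an atlas table violates the 90-region contract."""


class Region(NamedTuple):
    index: int  # 1-based atlas index
    name: str
    abbreviation: str
    lobe: str


# (stem name, stem abbreviation) for homologous left/right pairs; entry i
# yields atlas indices 2*i+1 (left) and 2*i+2 (right).
_REGION_PAIRS: Sequence[tuple[str, str]] = (
    ("Precentral gyrus", "PreCG"),
    ("Superior frontal gyrus (dorsal)", "SFGdor"),
    ("Orbitofrontal cortex (superior)", "ORBsup"),
    ("Middle frontal gyrus", "MFG"),
    ("Orbitofrontal cortex (middle)", "ORBmid"),
    ("Inferior frontal gyrus (opercular)", "IFGoperc"),
    ("Inferior frontal gyrus (triangular)", "IFGtriang"),
    ("Orbitofrontal cortex (inferior)", "ORBinf"),
    ("Rolandic operculum", "ROL"),
    ("Supplementary motor area", "SMA"),
    ("Olfactory cortex", "OLF"),
    ("Superior frontal gyrus (medial)", "SFGmed"),
    ("Orbitofrontal cortex (medial)", "ORBmed"),
    ("Rectus gyrus", "REC"),
    ("Insula", "INS"),
    ("Anterior cingulate gyrus", "ACG"),
    ("Median cingulate gyrus", "DCG"),
    ("Posterior cingulate gyrus", "PCG"),
    ("Hippocampus", "HIP"),
    ("Parahippocampal gyrus", "PHG"),
    ("Amygdala", "AMYG"),
    ("Calcarine cortex", "CAL"),
    ("Cuneus", "CUN"),
    ("Lingual gyrus", "LING"),
    ("Superior occipital gyrus", "SOG"),
    ("Middle occipital gyrus", "MOG"),
    ("Inferior occipital gyrus", "IOG"),
    ("Fusiform gyrus", "FFG"),
    ("Postcentral gyrus", "PoCG"),
    ("Superior parietal gyrus", "SPG"),
    ("Inferior parietal lobule", "IPL"),
    ("Supramarginal gyrus", "SMG"),
    ("Angular gyrus", "ANG"),
    ("Precuneus", "PCUN"),
    ("Paracentral lobule", "PCL"),
    ("Caudate nucleus", "CAU"),
    ("Putamen", "PUT"),
    ("Pallidum", "PAL"),
    ("Thalamus", "THA"),
    ("Heschl gyrus", "HES"),
    ("Superior temporal gyrus", "STG"),
    ("Temporal pole (superior)", "TPOsup"),
    ("Middle temporal gyrus", "MTG"),
    ("Temporal pole (middle)", "TPOmid"),
    ("Inferior temporal gyrus", "ITG"),
)


def lobe_for_index(index: int) -> str:
    for lobe, ranges in LOBE_RANGES.items():
        if any(index in r for r in ranges):
            return lobe
    return UNLISTED_LOBE


def _builtin_regions() -> tuple[Region, ...]:
    regions = []
    for i, (name, abbrev) in enumerate(_REGION_PAIRS):
        for side, suffix in (("left", "L"), ("right", "R")):
            idx = 2 * i + (1 if side == "left" else 2)
            regions.append(
                Region(idx, f"{name} {side}", f"{abbrev}-{suffix}", lobe_for_index(idx))
            )
    return tuple(regions)


@dataclass(frozen=True)
class AtlasDefinition:
    """Ordered 90-region parcellation with lobe grouping."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if len(self.regions) != N_REGIONS:
            raise AtlasError(
                f"atlas must define exactly {N_REGIONS} regions, got {len(self.regions)}"
            )
        indices = [r.index for r in self.regions]
        if indices != list(range(1, N_REGIONS + 1)):
            raise AtlasError("atlas indices must be 1..90 in order with no gaps")
        abbrevs = [r.abbreviation for r in self.regions]
        if len(set(abbrevs)) != N_REGIONS:
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise AtlasError(f"duplicate abbreviations in atlas: {dupes}")

    def __len__(self) -> int:
        return N_REGIONS

    def region(self, index: int) -> Region:
        """Region record for a 1-based atlas index."""
        if not 1 <= index <= N_REGIONS:
            raise AtlasError(f"region index {index} outside 1..{N_REGIONS}")
        return self.regions[index - 1]

    def lobe_of(self, index: int) -> str:
        return self.region(index).lobe

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.regions)

    def index_of(self, abbreviation: str) -> int:
        for r in self.regions:
            if r.abbreviation == abbreviation:
                return r.index
        raise AtlasError(f"unknown region abbreviation {abbreviation!r}")


def load_atlas(source: str | Path = BUILTIN_ATLAS_TOKEN) -> AtlasDefinition:
    """Load an atlas from the builtin token or a TSV/CSV table.

    A file source must hold one row per region with columns
    ``index, name, abbreviation[, lobe]`` (header optional, tab- or
    comma-separated).  When the lobe column is absent it is derived from
    the builtin index ranges.
    """
    if isinstance(source, str) and source == BUILTIN_ATLAS_TOKEN:
        return AtlasDefinition(_builtin_regions())
    path = Path(source)
    if not path.exists():
        raise AtlasError(f"atlas source {source!r} is neither the builtin token nor a file")
    regions = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(","))]
        if parts[0].lower() in {"index", "idx"}:
            continue
        try:
            idx = int(parts[0])
        except ValueError as exc:
            raise AtlasError(f"non-integer region index in atlas row {line!r}") from exc
        name, abbrev = parts[1], parts[2]
        lobe = parts[3] if len(parts) > 3 else lobe_for_index(idx)
        regions.append(Region(idx, name, abbrev, lobe))
    regions.sort(key=lambda r: r.index)
    return AtlasDefinition(tuple(regions))
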