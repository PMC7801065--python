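"""Domain types shared across the pipeline.

Immunohistochemistry (IHC) expression is recorded on a four-level ordinal
scale (not detected / low / medium / high) both for normal tissues (per cell
type) and for tumors (per patient).  The types here are thin, validated
containers around that scale plus the auxiliary tables the screening funnel
consumes: patient-level staining counts per tumor type, surfaceome
membership, transcript abundances (FPKM) and curated validation flags.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import ValidationError


class OrdinalLevel(enum.IntEnum):
    """Four-level IHC staining scale; the integer value is the scoring weight."""

    NOT_DETECTED = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @classmethod
    def from_token(cls, token: str) -> "OrdinalLevel":
        """Parse a level token case-insensitively; 'moderate' is a synonym of medium."""
        key = token.strip().lower().replace("_", " ")
        try:
            return _LEVEL_TOKENS[key]
        except KeyError:
            raise ValidationError(f"unknown expression level token: {token!r}") from None

    def __str__(self) -> str:  # canonical export token
        return _LEVEL_NAMES[self]


_LEVEL_TOKENS: dict[str, OrdinalLevel] = {
    "not detected": OrdinalLevel.NOT_DETECTED,
    "low": OrdinalLevel.LOW,
    "medium": OrdinalLevel.MEDIUM,
    "moderate": OrdinalLevel.MEDIUM,
    "high": OrdinalLevel.HIGH,
}

_LEVEL_NAMES: dict[OrdinalLevel, str] = {
    OrdinalLevel.NOT_DETECTED: "Not detected",
    OrdinalLevel.LOW: "Low",
    OrdinalLevel.MEDIUM: "Medium",
    OrdinalLevel.HIGH: "High",
}


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with its screening-relevant annotations."""

    gene_id: str
    gene_symbol: str
    is_membrane: bool = True
    has_protein_evidence: bool = True

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be nonempty")


@dataclass
class NormalTissueProfile:
    """Per-gene map of (normal tissue, cell type) -> staining level."""

    gene_id: str
    levels: dict[tuple[str, str], OrdinalLevel] = field(default_factory=dict)

    def tissues(self) -> set[str]:
        return {tissue for tissue, _ in self.levels}

    def tissue_level(self, tissue: str) -> OrdinalLevel | None:
        """Tissue-level staining: the maximum over the tissue's cell types."""
        hits = [lvl for (t, _), lvl in self.levels.items() if t == tissue]
        return max(hits) if hits else None


@dataclass(frozen=True)
class TumorLevelCounts:
    """Patient counts per staining category for one (gene, tumor type) pair."""

    gene_id: str
    tumor_type: str
    n_high: int = 0
    n_medium: int = 0
    n_low: int = 0
    n_not_detected: int = 0

    def __post_init__(self) -> None:
        for name in ("n_high", "n_medium", "n_low", "n_not_detected"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(
                    f"{self.gene_id}/{self.tumor_type}: negative count {name}={v}"
                )

    @property
    def total(self) -> int:
        return self.n_high + self.n_medium + self.n_low + self.n_not_detected


@dataclass(frozen=True)
class SurfaceomeSet:
    """Predicted cell-surface proteins (antibody-accessible targets)."""

    members: frozenset[str] = frozenset()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)


@dataclass
class FpkmTable:
    """Transcript abundance per (gene, tumor type); absent key means unassayed."""

    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (g, t), v in self.values.items():
            if v < 0:
                raise ValidationError(f"negative FPKM for {g}/{t}: {v}")

    def get(self, gene_id: str, tumor_type: str) -> float | None:
        return self.values.get((gene_id, tumor_type))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ValidationFlags:
    """Curated per-gene validation verdicts (transcript consistency, literature, staining pattern)."""

    rna_consistent: bool
    literature_conform: bool
    membranous_staining: bool


@dataclass
class HpaDataset:
    """All inputs the funnel consumes, in memory.

    ``profiles`` has an entry only for genes with protein-level evidence;
    ``fpkm`` and ``flags`` are optional because the screening stages do not
    need them (only validation does).
    """

    genes: list[GeneRecord]
    profiles: dict[str, NormalTissueProfile]
    pathology: list[TumorLevelCounts]
    surfaceome: SurfaceomeSet
    fpkm: FpkmTable | None = None
    flags: Mapping[str, ValidationFlags] | None = None

    def symbol_of(self, gene_id: str) -> str:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g.gene_symbol
        return gene_id
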