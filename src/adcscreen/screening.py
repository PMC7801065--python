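"""The multi-stage screening funnel for antibody-drug-conjugate targets.

Stages, in order:

1. membrane class — only predicted membrane-protein genes enter;
2. protein evidence — genes without IHC tissue data are excluded;
3. critical normal tissues — genes staining *high* (maximum over cell
   types) in any of the 13 critical tissues are excluded; medium staining
   never excludes;
4. quasi H-score threshold — genes are kept iff the cohort-level quasi
   H-score reaches the cutoff (default 150, inclusive) in at least one
   tumor type;
5. surfaceome — intersection with the predicted cell-surface proteome.

The quasi H-score for one (gene, tumor type) cohort is

    100 * (1*n_low + 2*n_medium + 3*n_high) / n_total,

where ``n_total`` counts every assayed patient including the *not detected*
ones (weight 0), so the score lives on the same 0-300 scale as the per-core
H-score and saturates at 300 only when every patient stains high.  A cohort
with zero assayed patients has an *undefined* score — never 0 — and an
undefined score never satisfies the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .types import (
    GeneRecord,
    HpaDataset,
    NormalTissueProfile,
    OrdinalLevel,
    SurfaceomeSet,
    TumorLevelCounts,
)
from .vocab import CRITICAL_TISSUES, NORMAL_TISSUES, TUMOR_TYPES

DEFAULT_CUTOFF = 150.0

STAGE_MEMBRANE = "membrane_class"
STAGE_EVIDENCE = "protein_evidence"
STAGE_CRITICAL = "critical_normal"
STAGE_THRESHOLD = "score_threshold"
STAGE_SURFACEOME = "surfaceome"
STAGE_ORDER = (STAGE_MEMBRANE, STAGE_EVIDENCE, STAGE_CRITICAL, STAGE_THRESHOLD, STAGE_SURFACEOME)


@dataclass(frozen=True)
class CriticalTissueSet:
    """Normal tissues where high target expression disqualifies a gene."""

    tissues: frozenset[str] = CRITICAL_TISSUES

    def __post_init__(self) -> None:
        unknown = self.tissues - set(NORMAL_TISSUES)
        if unknown:
            raise ValidationError(f"unknown critical tissue(s): {sorted(unknown)}")

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.tissues

    def __len__(self) -> int:
        return len(self.tissues)


@dataclass
class QuasiHScoreMatrix:
    """Defined quasi H-scores keyed by (gene_id, tumor_type); absent = undefined."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    tumor_types: tuple[str, ...] = TUMOR_TYPES

    def get(self, gene_id: str, tumor_type: str) -> float | None:
        return self.scores.get((gene_id, tumor_type))

    def gene_scores(self, gene_id: str) -> dict[str, float]:
        return {t: s for (g, t), s in self.scores.items() if g == gene_id}

    def gene_max(self, gene_id: str) -> float | None:
        vals = [s for (g, _), s in self.scores.items() if g == gene_id]
        return max(vals) if vals else None

    def genes(self) -> set[str]:
        return {g for g, _ in self.scores}

    def to_frame(self) -> pd.DataFrame:
        """Genes x tumor types frame with NaN for undefined cells."""
        genes = sorted(self.genes())
        df = pd.DataFrame(index=genes, columns=list(self.tumor_types), dtype=float)
        for (g, t), s in self.scores.items():
            df.loc[g, t] = s
        return df


@dataclass(frozen=True)
class StageRecord:
    name: str
    n_in: int
    n_out: int
    excluded: tuple[str, ...]


@dataclass
class ScreeningAudit:
    """Ordered record of the funnel; output counts must telescope."""

    stages: list[StageRecord] = field(default_factory=list)

    def add(self, name: str, retained: Iterable[str], excluded: Iterable[str]) -> None:
        retained, excluded = list(retained), sorted(excluded)
        self.stages.append(
            StageRecord(name, n_in=len(retained) + len(excluded),
                        n_out=len(retained), excluded=tuple(excluded))
        )

    def check(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_in != prev.n_out:
                raise ValidationError(
                    f"audit broken between {prev.name} and {cur.name}: "
                    f"{prev.n_out} != {cur.n_in}"
                )
        for s in self.stages:
            if s.n_out > s.n_in:
                raise ValidationError(f"stage {s.name} gained genes")

    def exit_stage(self, gene_id: str) -> str | None:
        """Name of the stage at which a gene left the funnel, or None."""
        for s in self.stages:
            if gene_id in s.excluded:
                return s.name
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_out"],
        )


@dataclass
class ScreenConfig:
    cutoff: float = DEFAULT_CUTOFF
    critical: CriticalTissueSet = field(default_factory=CriticalTissueSet)
    tumor_types: tuple[str, ...] = TUMOR_TYPES

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff <= 300.0):
            raise ConfigError(f"cutoff must be in (0, 300], got {self.cutoff}")


@dataclass
class ScreeningResult:
    potential: set[str]
    matrix: QuasiHScoreMatrix
    audit: ScreeningAudit


# ---------------------------------------------------------------------------
# stage operations


def filter_membrane(genes: Sequence[GeneRecord]) -> tuple[list[GeneRecord], list[GeneRecord]]:
    retained = [g for g in genes if g.is_membrane]
    excluded = [g for g in genes if not g.is_membrane]
    return retained, excluded


def filter_protein_evidence(
    genes: Sequence[GeneRecord],
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Partition genes by presence of protein-level (IHC) evidence."""
    retained = [g for g in genes if g.has_protein_evidence]
    excluded = [g for g in genes if not g.has_protein_evidence]
    return retained, excluded


def filter_critical_normal(
    profiles: Sequence[NormalTissueProfile],
    critical: CriticalTissueSet | None = None,
) -> tuple[list[NormalTissueProfile], list[NormalTissueProfile]]:
    """Exclude genes staining high in any critical normal tissue.

    A gene is excluded iff the maximum level over all cell types within any
    critical tissue is *high*; medium staining anywhere never excludes.
    """
    critical = critical or CriticalTissueSet()
    vocab = set(NORMAL_TISSUES)
    retained: list[NormalTissueProfile] = []
    excluded: list[NormalTissueProfile] = []
    for p in profiles:
        unknown = p.tissues() - vocab
        if unknown:
            raise ValidationError(
                f"gene {p.gene_id}: unknown normal tissue(s) {sorted(unknown)}"
            )
        is_high = any(
            p.tissue_level(t) == OrdinalLevel.HIGH
            for t in p.tissues()
            if t in critical
        )
        (excluded if is_high else retained).append(p)
    return retained, excluded


def quasi_h_score(counts: TumorLevelCounts) -> float | None:
    """Cohort quasi H-score in [0, 300]; None when no patients were assayed."""
    total = counts.total
    if total == 0:
        return None
    return 100.0 * (counts.n_low + 2 * counts.n_medium + 3 * counts.n_high) / total


def score_matrix(
    pathology: Sequence[TumorLevelCounts],
    tumor_types: tuple[str, ...] = TUMOR_TYPES,
) -> QuasiHScoreMatrix:
    scores: dict[tuple[str, str], float] = {}
    for row in pathology:
        s = quasi_h_score(row)
        if s is not None:
            scores[(row.gene_id, row.tumor_type)] = s
    return QuasiHScoreMatrix(scores=scores, tumor_types=tumor_types)


def threshold_filter(
    matrix: QuasiHScoreMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    genes: Iterable[str] | None = None,
) -> tuple[set[str], dict[str, float]]:
    """Keep genes with a defined score >= cutoff in at least one tumor type.

    Returns the retained gene set and the per-gene maximum defined score
    (genes with no defined score at all are absent from the map).
    The comparison is inclusive and carried out in double precision with no
    added tolerance; integer-count scores hitting the boundary exactly pass.
    """
    if not (0.0 < cutoff <= 300.0):
        raise ConfigError(f"cutoff must be in (0, 300], got {cutoff}")
    pool = set(genes) if genes is not None else matrix.genes()
    max_scores = {g: m for g in pool if (m := matrix.gene_max(g)) is not None}
    retained = {g for g, m in max_scores.items() if m >= cutoff}
    return retained, max_scores


def surfaceome_filter(
    genes: Iterable[str], surfaceome: SurfaceomeSet
) -> tuple[set[str], set[str]]:
    genes = set(genes)
    retained = genes & surfaceome.members
    return retained, genes - retained


# ---------------------------------------------------------------------------
# full funnel


def run_screening(
    dataset: HpaDataset, config: ScreenConfig | None = None
) -> ScreeningResult:
    """Run the full funnel and return (potential target set, score matrix, audit)."""
    config = config or ScreenConfig()
    audit = ScreeningAudit()

    known = {g.gene_id for g in dataset.genes}
    for row in dataset.pathology:
        if row.gene_id not in known:
            raise ValidationError(f"pathology row references unknown gene {row.gene_id}")

    genes = sorted(dataset.genes, key=lambda g: g.gene_id)

    kept, dropped = filter_membrane(genes)
    audit.add(STAGE_MEMBRANE, [g.gene_id for g in kept], [g.gene_id for g in dropped])

    kept, dropped = filter_protein_evidence(kept)
    audit.add(STAGE_EVIDENCE, [g.gene_id for g in kept], [g.gene_id for g in dropped])

    profiles = [dataset.profiles[g.gene_id] for g in kept if g.gene_id in dataset.profiles]
    kept_p, dropped_p = filter_critical_normal(profiles, config.critical)
    kept_ids = {p.gene_id for p in kept_p}
    audit.add(STAGE_CRITICAL, sorted(kept_ids), sorted(p.gene_id for p in dropped_p))

    matrix = score_matrix(
        [r for r in dataset.pathology if r.gene_id in kept_ids], config.tumor_types
    )
    retained, _ = threshold_filter(matrix, config.cutoff, genes=kept_ids)
    audit.add(STAGE_THRESHOLD, sorted(retained), sorted(kept_ids - retained))

    potential, dropped_s = surfaceome_filter(retained, dataset.surfaceome)
    audit.add(STAGE_SURFACEOME, sorted(potential), sorted(dropped_s))

    audit.check()
    return ScreeningResult(potential=potential, matrix=matrix, audit=audit)
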