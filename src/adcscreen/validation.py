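"""Three-flag validation of potential targets and prioritization summaries.

A potential target becomes a *candidate* only if it passes all three
validation checks: consistency between its IHC-derived quasi H-scores and
transcript abundance (RNA consistency), conformity with the published
literature, and a predominantly membranous staining pattern.  Literature
conformity and the staining verdict are curated inputs; RNA consistency can
additionally be recomputed from the data under a configurable rule.

Because no quantitative definition of "consistency" between the ordinal IHC
scores and FPKM is canonical, two rules are provided:

* ``spearman`` (default) — consistent iff the Spearman rank correlation of
  quasi H-score vs FPKM across tumor types with both values defined is at
  least ``threshold`` (default 0.3) with at least ``min_pairs`` (default 5)
  pairs;
* ``support`` — consistent iff FPKM exceeds ``fpkm_floor`` (default 1.0) in
  every tumor type where the quasi H-score reaches 150.

With fewer than ``min_pairs`` informative pairs the verdict is
*indeterminate*, which counts as a failure by default (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .errors import ConfigError, ValidationError
from .screening import DEFAULT_CUTOFF, QuasiHScoreMatrix
from .types import FpkmTable, NormalTissueProfile, OrdinalLevel, ValidationFlags
from .vocab import NORMAL_TISSUES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RnaRule:
    method: str = "spearman"
    threshold: float = 0.3
    min_pairs: int = 5
    fpkm_floor: float = 1.0
    indeterminate_passes: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "support"):
            raise ConfigError(f"unknown RNA-consistency method {self.method!r}")
        if self.min_pairs < 2:
            raise ConfigError("min_pairs must be >= 2")


@dataclass(frozen=True)
class RnaResult:
    gene_id: str
    consistent: bool
    statistic: float | None  # Spearman r for the default rule
    n_pairs: int
    indeterminate: bool = False


def rna_consistency(
    gene_id: str,
    matrix: QuasiHScoreMatrix,
    fpkm: FpkmTable,
    rule: RnaRule | None = None,
) -> RnaResult:
    """Judge IHC/RNA concordance for one gene under the configured rule."""
    rule = rule or RnaRule()
    scores = matrix.gene_scores(gene_id)
    pairs = [
        (s, f)
        for t, s in scores.items()
        if (f := fpkm.get(gene_id, t)) is not None
    ]
    n = len(pairs)
    if rule.method == "support":
        hot = [f for s, f in pairs if s >= DEFAULT_CUTOFF]
        return RnaResult(gene_id, all(f > rule.fpkm_floor for f in hot), None, n)
    if n < rule.min_pairs:
        log.info("gene %s: only %d IHC/FPKM pairs; RNA consistency indeterminate", gene_id, n)
        return RnaResult(gene_id, rule.indeterminate_passes, None, n, indeterminate=True)
    xs, ys = zip(*pairs)
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return RnaResult(gene_id, rule.indeterminate_passes, None, n, indeterminate=True)
    r = float(stats.spearmanr(xs, ys).statistic)
    return RnaResult(gene_id, r >= rule.threshold, r, n)


@dataclass(frozen=True)
class ValidationRecord:
    gene_id: str
    rna_consistent: bool
    literature_conform: bool
    membranous_staining: bool

    @property
    def is_candidate(self) -> bool:
        return self.rna_consistent and self.literature_conform and self.membranous_staining


def apply_validation(
    potential: set[str],
    flags: Mapping[str, ValidationFlags],
    rna_results: Mapping[str, RnaResult] | None = None,
) -> list[ValidationRecord]:
    """Combine the three verdicts for every potential target.

    The RNA verdict comes from ``rna_results`` when supplied (computed from
    the data) and from the curated flag otherwise.  Candidates are the
    records with all three verdicts true.
    """
    missing = sorted(g for g in potential if g not in flags)
    if missing:
        raise ValidationError(f"missing validation flags for gene(s): {missing}")
    records = []
    for gene_id in sorted(potential):
        f = flags[gene_id]
        rna = (
            rna_results[gene_id].consistent
            if rna_results is not None and gene_id in rna_results
            else f.rna_consistent
        )
        records.append(
            ValidationRecord(gene_id, rna, f.literature_conform, f.membranous_staining)
        )
    return records


def candidate_set(records: Sequence[ValidationRecord]) -> set[str]:
    return {r.gene_id for r in records if r.is_candidate}


# ---------------------------------------------------------------------------
# prioritization


@dataclass(frozen=True)
class PriorityProfile:
    """Per-candidate summary used to rank targets.

    ``n_tumors_ge_cutoff`` counts tumor types whose quasi H-score reaches the
    cutoff (tumor-overexpression breadth); the normal-tissue counters predict
    on-target off-tumor toxicity over the 45-tissue vocabulary, aggregating
    each tissue as the maximum over its cell types.
    """

    gene_id: str
    max_quasi_h: float
    n_tumors_ge_cutoff: int
    n_normal_high_or_medium: int
    n_normal_high: int


def priority_profile(
    gene_id: str,
    matrix: QuasiHScoreMatrix,
    normal_profile: NormalTissueProfile,
    cutoff: float = DEFAULT_CUTOFF,
) -> PriorityProfile:
    scores = matrix.gene_scores(gene_id)
    tissue_levels = [
        lvl for t in NORMAL_TISSUES if (lvl := normal_profile.tissue_level(t)) is not None
    ]
    return PriorityProfile(
        gene_id=gene_id,
        max_quasi_h=max(scores.values(), default=float("nan")),
        n_tumors_ge_cutoff=sum(1 for s in scores.values() if s >= cutoff),
        n_normal_high_or_medium=sum(1 for l in tissue_levels if l >= OrdinalLevel.MEDIUM),
        n_normal_high=sum(1 for l in tissue_levels if l == OrdinalLevel.HIGH),
    )


def rank_candidates(records: Sequence[PriorityProfile]) -> list[PriorityProfile]:
    """Total, deterministic order: strongest and broadest tumor overexpression
    first, narrower normal-tissue footprint preferred, gene id as tie-break."""
    return sorted(
        records,
        key=lambda r: (-r.max_quasi_h, -r.n_tumors_ge_cutoff,
                       r.n_normal_high_or_medium, r.gene_id),
    )
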