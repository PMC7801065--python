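"""Seeded generator of atlas-shaped datasets with planted ground truth.

Every simulated gene belongs to exactly one class that names the funnel
stage (or validation flag) it is designed to fail, while passing every
earlier stage:

* ``candidate`` — survives the whole pipeline;
* ``non_membrane`` — not in the predicted-membrane-protein class;
* ``no_evidence`` — membrane gene without IHC tissue data;
* ``critical_normal_high`` — stains high in at least one critical tissue;
* ``low_score`` — quasi H-score below 150 in every tumor type;
* ``non_surface_high`` — scores >= 150 somewhere but is not in the
  predicted surfaceome;
* ``fails_rna`` / ``fails_literature`` / ``fails_membranous`` — surface
  proteins scoring >= 150 that carry exactly one false validation flag.

Patient counts per (gene, tumor type) are multinomial draws over the four
staining categories with class-conditional weights; draws are rejected and
resampled until the score constraint the class requires provably holds
(>= 150 in a designated tumor type for high-scoring classes, < 150
everywhere for ``low_score``).  FPKM values are tied to each gene's score
ranks through a Gaussian copula whose correlation is ``rna_concordance``
for concordant genes and 0 for ``fails_rna`` genes.  Identical
configurations and seeds produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import hpa_io
from .errors import ConfigError
from .ihc import CoreReading
from .screening import DEFAULT_CUTOFF, quasi_h_score
from .types import (
    FpkmTable,
    GeneRecord,
    HpaDataset,
    NormalTissueProfile,
    OrdinalLevel,
    SurfaceomeSet,
    TumorLevelCounts,
    ValidationFlags,
)
from .vocab import CRITICAL_TISSUES, FPKM_TUMOR_TYPES, NORMAL_TISSUES, TUMOR_TYPES

CLASS_LABELS = (
    "candidate",
    "non_membrane",
    "no_evidence",
    "critical_normal_high",
    "low_score",
    "non_surface_high",
    "fails_rna",
    "fails_literature",
    "fails_membranous",
)

#: Default mix: 23 planted candidates (the size of the published candidate
#: panel) plus a screening decoy cohort per exclusion reason.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "candidate": 23,
    "non_membrane": 20,
    "no_evidence": 20,
    "critical_normal_high": 20,
    "low_score": 20,
    "non_surface_high": 20,
    "fails_rna": 5,
    "fails_literature": 5,
    "fails_membranous": 5,
}

# multinomial weights over (not detected, low, medium, high)
_P_DESIGNATED = (0.05, 0.05, 0.20, 0.70)  # tumor types where the class must score >= 150
_P_BACKGROUND = (0.45, 0.30, 0.20, 0.05)  # unconstrained tumor types
_P_CRIT_TISSUE = (0.55, 0.30, 0.15)       # critical-tissue levels, high never drawn
_P_TISSUE = (0.40, 0.30, 0.20, 0.10)      # non-critical normal-tissue levels

_CELL_TYPES = ("glandular cells", "squamous epithelial cells", "endothelial cells")

_HIGH_CLASSES = frozenset(
    {"candidate", "non_surface_high", "fails_rna", "fails_literature", "fails_membranous"}
)
_SURFACE_CLASSES = frozenset(
    {"candidate", "fails_rna", "fails_literature", "fails_membranous",
     "no_evidence", "critical_normal_high", "low_score"}
)


@dataclass
class SimConfig:
    n_genes_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    tumor_types: tuple[str, ...] = TUMOR_TYPES
    normal_tissues: tuple[str, ...] = NORMAL_TISSUES
    fpkm_tumor_types: tuple[str, ...] = FPKM_TUMOR_TYPES
    patients_per_tumor: int = 12
    rna_concordance: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_genes_per_class) - set(CLASS_LABELS)
        if unknown:
            raise ConfigError(f"unknown gene class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.n_genes_per_class.values()):
            raise ConfigError("class counts must be >= 0")
        if self.patients_per_tumor < 1:
            raise ConfigError("patients_per_tumor must be >= 1")
        if not (-1.0 <= self.rna_concordance <= 1.0):
            raise ConfigError("rna_concordance must be in [-1, 1]")
        if not CRITICAL_TISSUES <= set(self.normal_tissues):
            raise ConfigError("normal_tissues must contain all 13 critical tissues")


@dataclass
class GroundTruth:
    """gene_id -> planted class label (exactly one per gene)."""

    labels: dict[str, str] = field(default_factory=dict)

    def of_class(self, *classes: str) -> set[str]:
        return {g for g, c in self.labels.items() if c in classes}


def simulate_dataset(config: SimConfig | None = None) -> tuple[HpaDataset, GroundTruth]:
    """Generate one dataset; same config and seed give identical output."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    genes: list[GeneRecord] = []
    profiles: dict[str, NormalTissueProfile] = {}
    pathology: list[TumorLevelCounts] = []
    surface: set[str] = set()
    flags: dict[str, ValidationFlags] = {}
    truth = GroundTruth()

    idx = 0
    for label in CLASS_LABELS:
        for _ in range(config.n_genes_per_class.get(label, 0)):
            idx += 1
            gene_id = f"ENSG{idx:011d}"
            symbol = f"G{idx:04d}"
            truth.labels[gene_id] = label

            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    gene_symbol=symbol,
                    is_membrane=label != "non_membrane",
                    has_protein_evidence=label != "no_evidence",
                )
            )
            if label != "no_evidence":
                profiles[gene_id] = _draw_profile(rng, gene_id, label, config)
            pathology.extend(_draw_counts(rng, gene_id, label, config))
            if label in _SURFACE_CLASSES:
                surface.add(gene_id)
            flags[gene_id] = ValidationFlags(
                rna_consistent=label != "fails_rna",
                literature_conform=label != "fails_literature",
                membranous_staining=label != "fails_membranous",
            )

    fpkm = _draw_fpkm(rng, pathology, truth, config)
    dataset = HpaDataset(
        genes=genes,
        profiles=profiles,
        pathology=pathology,
        surfaceome=SurfaceomeSet(members=frozenset(surface)),
        fpkm=fpkm,
        flags=flags,
    )
    return dataset, truth


def _draw_profile(
    rng: np.random.Generator, gene_id: str, label: str, config: SimConfig
) -> NormalTissueProfile:
    profile = NormalTissueProfile(gene_id=gene_id)
    for tissue in config.normal_tissues:
        n_ct = int(rng.integers(1, 3))
        cell_types = list(rng.choice(_CELL_TYPES, size=n_ct, replace=False))
        for ct in cell_types:
            if tissue in CRITICAL_TISSUES:
                lvl = OrdinalLevel(int(rng.choice(3, p=_P_CRIT_TISSUE)))
            else:
                lvl = OrdinalLevel(int(rng.choice(4, p=_P_TISSUE)))
            profile.levels[(tissue, ct)] = lvl
    if label == "critical_normal_high":
        n_hot = int(rng.integers(1, 4))
        hot = rng.choice(sorted(CRITICAL_TISSUES), size=n_hot, replace=False)
        for tissue in hot:
            profile.levels[(str(tissue), _CELL_TYPES[0])] = OrdinalLevel.HIGH
    return profile


def _draw_counts(
    rng: np.random.Generator, gene_id: str, label: str, config: SimConfig
) -> list[TumorLevelCounts]:
    n = config.patients_per_tumor
    designated: set[str] = set()
    if label in _HIGH_CLASSES:
        n_hot = int(rng.integers(1, 4))
        designated = {
            str(t) for t in rng.choice(config.tumor_types, size=n_hot, replace=False)
        }
    rows = []
    for tumor in config.tumor_types:
        if tumor in designated:
            counts = _rejection_draw(rng, n, _P_DESIGNATED, lambda s: s >= DEFAULT_CUTOFF)
        elif label == "low_score":
            counts = _rejection_draw(rng, n, _P_BACKGROUND, lambda s: s < DEFAULT_CUTOFF)
        else:
            counts = rng.multinomial(n, _P_BACKGROUND)
        rows.append(
            TumorLevelCounts(
                gene_id=gene_id,
                tumor_type=tumor,
                n_not_detected=int(counts[0]),
                n_low=int(counts[1]),
                n_medium=int(counts[2]),
                n_high=int(counts[3]),
            )
        )
    return rows


def _rejection_draw(rng, n, p, ok, max_tries=1000):
    for _ in range(max_tries):
        c = rng.multinomial(n, p)
        score = 100.0 * (c[1] + 2 * c[2] + 3 * c[3]) / n
        if ok(score):
            return c
    raise ConfigError("rejection sampling failed; constraint unsatisfiable")  # pragma: no cover


def _draw_fpkm(
    rng: np.random.Generator,
    pathology: Sequence[TumorLevelCounts],
    truth: GroundTruth,
    config: SimConfig,
) -> FpkmTable:
    """FPKM tied to each gene's score ranks by a Gaussian copula."""
    by_gene: dict[str, dict[str, float]] = {}
    for row in pathology:
        s = quasi_h_score(row)
        if s is not None and row.tumor_type in config.fpkm_tumor_types:
            by_gene.setdefault(row.gene_id, {})[row.tumor_type] = s
    values: dict[tuple[str, str], float] = {}
    for gene_id in sorted(by_gene):
        rho = 0.0 if truth.labels[gene_id] == "fails_rna" else config.rna_concordance
        tumors = [t for t in config.fpkm_tumor_types if t in by_gene[gene_id]]
        s = np.array([by_gene[gene_id][t] for t in tumors])
        m = len(s)
        # average ranks with seeded jitter to break ties, then normal scores
        jitter = rng.normal(0.0, 1e-9, size=m)
        ranks = stats.rankdata(s + jitter, method="ordinal")
        z = stats.norm.ppf((ranks - 0.5) / m)
        eps = rng.normal(0.0, 1.0, size=m)
        zf = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        fpkm = np.exp(0.5 + 1.0 * zf)  # log-normal abundances, median ~1.6
        for t, v in zip(tumors, fpkm):
            values[(gene_id, t)] = float(v)
    return FpkmTable(values=values)


# ---------------------------------------------------------------------------
# TMA core simulation


def simulate_tma_cores(
    n_tumors: int,
    mean_hscore: float,
    sd: float,
    cores_per_tumor: int = 3,
    dropout_rate: float = 0.0,
    seed: int = 0,
    core_scatter: float = 10.0,
) -> list[tuple[str, list[CoreReading]]]:
    """Simulate per-tumor core readings with target H-score mean and SD.

    Per-tumor scores are drawn from a Beta distribution scaled to [0, 300]
    whose parameters are moment-matched to (``mean_hscore``, ``sd``), so the
    population mean and SD equal the targets with no truncation bias; each
    tumor's cores scatter around its score with zero-mean deviations so the
    per-tumor mean is preserved exactly (cores fall back to the tumor score
    when a deviation would leave the scale).  A fraction ``dropout_rate`` of
    cores is flagged as containing no tumor cells.
    """
    if not (0.0 <= mean_hscore <= 300.0):
        raise ConfigError(f"mean_hscore must be in [0, 300], got {mean_hscore}")
    if sd < 0 or not (0.0 <= dropout_rate <= 1.0) or cores_per_tumor < 1 or n_tumors < 0:
        raise ConfigError("invalid TMA simulation parameters")
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        tumor_scores = np.full(n_tumors, mean_hscore)
    else:
        m, s = mean_hscore / 300.0, sd / 300.0
        if s * s >= m * (1.0 - m):
            raise ConfigError(
                f"sd={sd} is unattainable on [0, 300] with mean {mean_hscore}"
            )
        nu = m * (1.0 - m) / (s * s) - 1.0
        tumor_scores = 300.0 * rng.beta(m * nu, (1.0 - m) * nu, size=n_tumors)
    out: list[tuple[str, list[CoreReading]]] = []
    for i, target in enumerate(tumor_scores, start=1):
        dev = rng.normal(0.0, core_scatter, size=cores_per_tumor)
        dev -= dev.mean()
        core_scores = target + dev
        if np.any(core_scores < 0.0) or np.any(core_scores > 300.0):
            core_scores = np.full(cores_per_tumor, target)
        dropped = rng.random(cores_per_tumor) < dropout_rate
        cores = [
            _reading_from_score(float(s), has_tumor_cells=not bool(d))
            for s, d in zip(core_scores, dropped)
        ]
        out.append((f"T{i:03d}", cores))
    return out


def _reading_from_score(score: float, has_tumor_cells: bool = True) -> CoreReading:
    """Decompose a target H-score into a valid (intensity, percent) reading."""
    if score <= 0.0:
        return CoreReading(intensity=0, percent_positive=0.0, has_tumor_cells=has_tumor_cells)
    intensity = min(3, max(1, math.ceil(score / 100.0)))
    return CoreReading(
        intensity=intensity,
        percent_positive=score / intensity,
        has_tumor_cells=has_tumor_cells,
    )


# ---------------------------------------------------------------------------
# file output


DATASET_FILES = {
    "genes": "genes.xml",
    "pathology": "pathology.tsv",
    "surfaceome": "surfaceome.tsv",
    "fpkm": "fpkm.tsv",
    "flags": "flags.tsv",
    "ground_truth": "ground_truth.tsv",
}


def write_dataset(
    dataset: HpaDataset, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write every table of a simulated dataset in its external dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in DATASET_FILES.items()}
    pairs = [
        (g, dataset.profiles.get(g.gene_id, NormalTissueProfile(gene_id=g.gene_id)))
        for g in dataset.genes
    ]
    hpa_io.write_gene_xml(paths["genes"], pairs)
    symbols = {g.gene_id: g.gene_symbol for g in dataset.genes}
    hpa_io.write_pathology_tsv(paths["pathology"], dataset.pathology, symbols)
    hpa_io.write_surfaceome_tsv(paths["surfaceome"], dataset.surfaceome)
    hpa_io.write_fpkm_tsv(paths["fpkm"], dataset.fpkm or FpkmTable())
    hpa_io.write_flags_tsv(paths["flags"], dataset.flags or {})
    hpa_io.write_ground_truth_tsv(paths["ground_truth"], truth.labels)
    return paths


def load_dataset(in_dir: str | Path) -> tuple[HpaDataset, GroundTruth | None]:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    pairs = hpa_io.read_membrane_gene_table(in_dir / DATASET_FILES["genes"])
    genes = [g for g, _ in pairs]
    profiles = {p.gene_id: p for _, p in pairs if p.levels}
    pathology = hpa_io.read_pathology_counts(in_dir / DATASET_FILES["pathology"])
    surfaceome = hpa_io.read_surfaceome(in_dir / DATASET_FILES["surfaceome"])
    fpkm_path = in_dir / DATASET_FILES["fpkm"]
    fpkm = hpa_io.read_fpkm(fpkm_path) if fpkm_path.exists() else None
    flags_path = in_dir / DATASET_FILES["flags"]
    flags = hpa_io.read_flags(flags_path) if flags_path.exists() else None
    truth_path = in_dir / DATASET_FILES["ground_truth"]
    truth = (
        GroundTruth(labels=hpa_io.read_ground_truth(truth_path))
        if truth_path.exists()
        else None
    )
    return (
        HpaDataset(genes=genes, profiles=profiles, pathology=pathology,
                   surfaceome=surfaceome, fpkm=fpkm, flags=flags),
        truth,
    )
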