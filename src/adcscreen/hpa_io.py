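"""Readers and writers for the tissue-atlas table dialects.

Four external table shapes are consumed:

* gene table — either a reduced XML export (gene id, symbol, protein-class
  membership, per-tissue/cell-type IHC levels; all other elements ignored)
  or the flat normal-tissue TSV (``Gene``, ``Gene name``, ``Tissue``,
  ``Cell type``, ``Level``, ``Reliability``);
* pathology TSV — per-(gene, cancer) patient counts in the four staining
  categories (``Gene``, ``Gene name``, ``Cancer``, ``High``, ``Medium``,
  ``Low``, ``Not detected``);
* surfaceome table — delimited text with an identifier column (``Gene``,
  ``GeneName`` or ``UniProt``);
* FPKM TSV — ``Gene``, ``Cancer``, ``FPKM``.

Gene identity is keyed on the stable (Ensembl-style) gene id throughout;
symbols are an alias map, and surfaceome rows keyed by symbol are resolved
through it, with unresolved rows logged and dropped.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

from .errors import ParseError, SchemaError, ValidationError
from .types import (
    FpkmTable,
    GeneRecord,
    NormalTissueProfile,
    OrdinalLevel,
    SurfaceomeSet,
    TumorLevelCounts,
    ValidationFlags,
)

log = logging.getLogger(__name__)

MEMBRANE_CLASS = "Predicted membrane proteins"

PATHOLOGY_COLUMNS = ("Gene", "Gene name", "Cancer", "High", "Medium", "Low", "Not detected")
NORMAL_TISSUE_COLUMNS = ("Gene", "Gene name", "Tissue", "Cell type", "Level", "Reliability")
SURFACEOME_ID_COLUMNS = ("Gene", "GeneName", "UniProt")
FPKM_COLUMNS = ("Gene", "Cancer", "FPKM")
TMA_COLUMNS = ("tumor_id", "core_id", "intensity", "percent_positive", "has_tumor_cells")


# ---------------------------------------------------------------------------
# gene table


def read_membrane_gene_table(
    path: str | Path, format_hint: str | None = None
) -> list[tuple[GeneRecord, NormalTissueProfile]]:
    """Read the gene export into (record, normal-tissue profile) pairs.

    ``format_hint`` may be ``"xml"`` or ``"tsv"``; when omitted it is taken
    from the file extension.  A gene whose entry carries no tissue-expression
    data has ``has_protein_evidence=False`` and an empty profile.
    """
    path = Path(path)
    fmt = format_hint or ("xml" if path.suffix.lower() == ".xml" else "tsv")
    if fmt == "xml":
        return _read_gene_xml(path)
    if fmt == "tsv":
        return _read_gene_tsv(path)
    raise ParseError(f"unknown gene-table format: {fmt!r}")


def _read_gene_xml(path: Path) -> list[tuple[GeneRecord, NormalTissueProfile]]:
    try:
        tree = etree.parse(str(path))
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: not well-formed XML: {exc}") from exc

    out: list[tuple[GeneRecord, NormalTissueProfile]] = []
    seen: set[str] = set()
    for entry in tree.getroot().iter("entry"):
        ident = entry.find("identifier")
        gene_id = ident.get("id") if ident is not None else None
        if not gene_id:
            raise ParseError(f"{path}: entry without an <identifier id=...> element")
        if gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        name = entry.findtext("name") or gene_id

        class_block = entry.find("proteinClasses")
        if class_block is None:
            is_membrane = True  # reduced dialect: unannotated entries pass through
        else:
            is_membrane = any(
                pc.get("name") == MEMBRANE_CLASS for pc in class_block.iter("proteinClass")
            )

        profile = NormalTissueProfile(gene_id=gene_id)
        expr = entry.find("tissueExpression")
        if expr is not None:
            for data in expr.iter("data"):
                tissue = data.findtext("tissue")
                cell_type = data.findtext("cellType") or ""
                token = data.findtext("level")
                if tissue is None or token is None:
                    raise ParseError(f"{path}: incomplete tissue data for {gene_id}")
                try:
                    level = OrdinalLevel.from_token(token)
                except ValidationError:
                    raise ParseError(
                        f"{path}: gene {gene_id}: unknown level token {token!r}"
                    ) from None
                profile.levels[(tissue, cell_type)] = level
        record = GeneRecord(
            gene_id=gene_id,
            gene_symbol=name,
            is_membrane=is_membrane,
            has_protein_evidence=bool(profile.levels),
        )
        out.append((record, profile))
    return out


def _read_gene_tsv(path: Path) -> list[tuple[GeneRecord, NormalTissueProfile]]:
    df = _read_tsv(path, NORMAL_TISSUE_COLUMNS[:5])  # Reliability optional
    pairs: dict[str, tuple[GeneRecord, NormalTissueProfile]] = {}
    for i, row in df.iterrows():
        line = int(i) + 2
        gene_id = str(row["Gene"])
        try:
            level = OrdinalLevel.from_token(str(row["Level"]))
        except ValidationError:
            raise ParseError(
                f"{path}:{line}: gene {gene_id}: unknown level token {row['Level']!r}"
            ) from None
        if gene_id not in pairs:
            pairs[gene_id] = (
                GeneRecord(gene_id, str(row["Gene name"]), is_membrane=True,
                           has_protein_evidence=True),
                NormalTissueProfile(gene_id=gene_id),
            )
        pairs[gene_id][1].levels[(str(row["Tissue"]), str(row["Cell type"]))] = level
    return list(pairs.values())


def write_gene_xml(
    path: str | Path, pairs: Iterable[tuple[GeneRecord, NormalTissueProfile]]
) -> None:
    root = etree.Element("proteinAtlas")
    for record, profile in pairs:
        entry = etree.SubElement(root, "entry")
        etree.SubElement(entry, "name").text = record.gene_symbol
        etree.SubElement(entry, "identifier", id=record.gene_id, db="Ensembl")
        classes = etree.SubElement(entry, "proteinClasses")
        if record.is_membrane:
            etree.SubElement(classes, "proteinClass", name=MEMBRANE_CLASS)
        if profile.levels:
            expr = etree.SubElement(entry, "tissueExpression")
            for (tissue, cell_type), level in sorted(profile.levels.items()):
                data = etree.SubElement(expr, "data")
                etree.SubElement(data, "tissue").text = tissue
                etree.SubElement(data, "cellType").text = cell_type
                etree.SubElement(data, "level").text = str(level)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def write_normal_tissue_tsv(
    path: str | Path, pairs: Iterable[tuple[GeneRecord, NormalTissueProfile]]
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(NORMAL_TISSUE_COLUMNS)
        for record, profile in pairs:
            for (tissue, cell_type), level in sorted(profile.levels.items()):
                w.writerow(
                    [record.gene_id, record.gene_symbol, tissue, cell_type, str(level), "Approved"]
                )


# ---------------------------------------------------------------------------
# pathology counts


def read_pathology_counts(path: str | Path) -> list[TumorLevelCounts]:
    """Read the pathology TSV; blank count cells are unassayed and read as 0."""
    df = _read_tsv(path, ("Gene", "Cancer"))
    out: list[TumorLevelCounts] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        counts = {}
        for col, attr in (
            ("High", "n_high"),
            ("Medium", "n_medium"),
            ("Low", "n_low"),
            ("Not detected", "n_not_detected"),
        ):
            raw = row.get(col)
            if raw is None or pd.isna(raw) or str(raw).strip() == "":
                counts[attr] = 0
                continue
            try:
                counts[attr] = int(float(raw))
            except (TypeError, ValueError):
                raise ParseError(f"{path}:{line}: non-integer count {col}={raw!r}") from None
        out.append(TumorLevelCounts(gene_id=str(row["Gene"]), tumor_type=str(row["Cancer"]), **counts))
    return out


def write_pathology_tsv(path: str | Path, rows: Iterable[TumorLevelCounts],
                        symbols: Mapping[str, str] | None = None) -> None:
    symbols = symbols or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PATHOLOGY_COLUMNS)
        for r in rows:
            w.writerow(
                [r.gene_id, symbols.get(r.gene_id, r.gene_id), r.tumor_type,
                 r.n_high, r.n_medium, r.n_low, r.n_not_detected]
            )


# ---------------------------------------------------------------------------
# surfaceome


def read_surfaceome(
    path: str | Path, symbol_to_id: Mapping[str, str] | None = None
) -> SurfaceomeSet:
    """Read the predicted-surfaceome table into a membership set.

    The identifier column is the first of ``Gene`` (stable id), ``GeneName``
    (symbol, resolved through ``symbol_to_id``) or ``UniProt`` (resolved the
    same way) present.  Unresolvable rows are logged and dropped.
    """
    df = _read_tsv(path, ())
    id_col = next((c for c in SURFACEOME_ID_COLUMNS if c in df.columns), None)
    if id_col is None:
        raise SchemaError(
            f"{path}: no identifier column among {SURFACEOME_ID_COLUMNS}"
        )
    members: set[str] = set()
    for raw in df[id_col].dropna():
        key = str(raw).strip()
        if not key:
            continue
        if id_col == "Gene":
            members.add(key)
        elif symbol_to_id is not None and key in symbol_to_id:
            members.add(symbol_to_id[key])
        else:
            log.warning("surfaceome row %r could not be resolved to a gene id; dropped", key)
    return SurfaceomeSet(members=frozenset(members))


def write_surfaceome_tsv(path: str | Path, surfaceome: SurfaceomeSet) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Gene"])
        for gene_id in sorted(surfaceome.members):
            w.writerow([gene_id])


# ---------------------------------------------------------------------------
# FPKM


def read_fpkm(path: str | Path) -> FpkmTable:
    df = _read_tsv(path, FPKM_COLUMNS)
    values: dict[tuple[str, str], float] = {}
    for i, row in df.iterrows():
        v = float(row["FPKM"])
        if v < 0:
            raise ValidationError(f"{path}:{int(i) + 2}: negative FPKM {v}")
        values[(str(row["Gene"]), str(row["Cancer"]))] = v
    return FpkmTable(values=values)


def write_fpkm_tsv(path: str | Path, table: FpkmTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(FPKM_COLUMNS)
        for (gene_id, tumor), v in sorted(table.values.items()):
            w.writerow([gene_id, tumor, f"{v:.6g}"])


# ---------------------------------------------------------------------------
# validation flags / ground truth / TMA readings


def read_flags(path: str | Path) -> dict[str, ValidationFlags]:
    df = _read_tsv(path, ("gene_id", "rna_consistent", "literature_conform", "membranous_staining"))
    return {
        str(r["gene_id"]): ValidationFlags(
            rna_consistent=bool(int(r["rna_consistent"])),
            literature_conform=bool(int(r["literature_conform"])),
            membranous_staining=bool(int(r["membranous_staining"])),
        )
        for _, r in df.iterrows()
    }


def write_flags_tsv(path: str | Path, flags: Mapping[str, ValidationFlags]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "rna_consistent", "literature_conform", "membranous_staining"])
        for gene_id in sorted(flags):
            f = flags[gene_id]
            w.writerow(
                [gene_id, int(f.rna_consistent), int(f.literature_conform), int(f.membranous_staining)]
            )


def read_ground_truth(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, ("gene_id", "class"))
    return {str(r["gene_id"]): str(r["class"]) for _, r in df.iterrows()}


def write_ground_truth_tsv(path: str | Path, labels: Mapping[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "class"])
        for gene_id in sorted(labels):
            w.writerow([gene_id, labels[gene_id]])


def read_tma_readings(path: str | Path) -> dict[str, list["CoreReading"]]:
    """Read per-core TMA stainings grouped by tumor id (insertion order kept)."""
    from .ihc import CoreReading  # local import to avoid a cycle

    df = _read_tsv(path, TMA_COLUMNS)
    out: dict[str, list[CoreReading]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["tumor_id"]), []).append(
            CoreReading(
                intensity=int(r["intensity"]),
                percent_positive=float(r["percent_positive"]),
                has_tumor_cells=bool(int(r["has_tumor_cells"])),
            )
        )
    return out


def write_tma_readings_tsv(
    path: str | Path, readings: Mapping[str, Sequence["CoreReading"]]
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TMA_COLUMNS)
        for tumor_id, cores in readings.items():
            for k, core in enumerate(cores, start=1):
                w.writerow(
                    [tumor_id, k, core.intensity, f"{core.percent_positive:.6g}",
                     int(core.has_tumor_cells)]
                )


# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    except Exception as exc:  # malformed delimiter structure
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df
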