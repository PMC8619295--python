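"""Gene-catalog loading, validation and census statistics.

The catalog is a TSV mirroring a published gene-superfamily table: one
row per locus with AGNC-style gene name, chromosome, genomic span,
strand, exon count and deduced-peptide descriptors.  Coordinates are
stored 1-based inclusive exactly as printed — minus-strand rows may have
start > end — and :attr:`GeneRecord.span` exposes the strand-agnostic
(low, high) interval used by positional analyses.  Unplaced loci sit on
chromosome ``"Un"`` with zero coordinates and are excluded from every
positional computation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

UNPLACED = "Un"

CATALOG_COLUMNS = [
    "gene_name",
    "locus_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "strand",
    "exon_count",
    "protein_length_aa",
    "molecular_weight_kda",
    "isoform_count",
    "isoelectric_point",
]

_FAMILY_RE = re.compile(r"ALDH(\d+)([A-Z])(\d+)$")


@dataclass(frozen=True)
class GeneRecord:
    """One catalog row; coordinates kept exactly as printed."""

    gene_name: str
    locus_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str
    exon_count: int
    protein_length: int
    molecular_weight: float
    isoform_count: int
    isoelectric_point: float

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED

    @property
    def span(self) -> tuple[int, int] | None:
        """Normalized (low, high) genomic interval; None when unplaced."""
        if not self.placed:
            return None
        return (min(self.start_bp, self.end_bp), max(self.start_bp, self.end_bp))

    @property
    def family(self) -> int | None:
        parsed = parse_gene_name(self.gene_name)
        return parsed[0] if parsed else None


def parse_gene_name(gene_name: str) -> tuple[int, str, int] | None:
    """Split an AGNC-style name into (family, subfamily, member).

    The root symbol ``ALDH`` is searched anywhere in the name so species
    prefixes (``CaALDH3H2``) parse transparently.  Returns None when the
    name does not follow the family/subfamily/member convention.
    """
    m = _FAMILY_RE.search(gene_name)
    if not m:
        return None
    return int(m.group(1)), m.group(2), int(m.group(3))


@dataclass
class CatalogSummary:
    """Census statistics over a catalog."""

    n_loci: int
    n_placed: int
    per_chromosome_counts: dict[str, int]
    per_family_counts: dict[int, int]
    protein_length_range: tuple[int, int]
    mw_range: tuple[float, float]
    pi_range: tuple[float, float]
    exon_range: tuple[int, int] | None
    unparsed_gene_names: list[str] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.per_family_counts)


def _records_from_frame(df: pd.DataFrame, source: str) -> list[GeneRecord]:
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {', '.join(missing)}")
    dup = df["locus_id"][df["locus_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{source}: duplicate locus_id: {', '.join(sorted(set(dup)))}")
    records = []
    for row in df.itertuples(index=False):
        rec = GeneRecord(
            gene_name=str(row.gene_name),
            locus_id=str(row.locus_id),
            chromosome=str(row.chromosome),
            start_bp=int(row.start_bp),
            end_bp=int(row.end_bp),
            strand=str(row.strand),
            exon_count=int(row.exon_count),
            protein_length=int(row.protein_length_aa),
            molecular_weight=float(row.molecular_weight_kda),
            isoform_count=int(row.isoform_count),
            isoelectric_point=float(row.isoelectric_point),
        )
        if rec.placed and min(rec.start_bp, rec.end_bp) < 1:
            raise ValidationError(f"{source}: placed locus {rec.locus_id} has coordinate < 1")
        if not rec.placed and (rec.start_bp != 0 or rec.end_bp != 0):
            raise ValidationError(f"{source}: unplaced locus {rec.locus_id} has nonzero coordinates")
        records.append(rec)
    return records


def load_catalog(path: str | Path) -> list[GeneRecord]:
    """Load a catalog TSV into GeneRecords (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty and list(df.columns):
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        return []
    return _records_from_frame(df, str(path))


def write_catalog(records: list[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                r.gene_name,
                r.locus_id,
                r.chromosome,
                r.start_bp,
                r.end_bp,
                r.strand,
                r.exon_count,
                r.protein_length,
                f"{r.molecular_weight:.2f}",
                r.isoform_count,
                f"{r.isoelectric_point:.2f}",
            )
            for r in records
        ],
        columns=CATALOG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def packaged_catalog_path() -> Path:
    """Path to the bundled chickpea ALDH superfamily catalog."""
    return Path(str(resources.files("aldh_curator").joinpath("data/caaldh_catalog.tsv")))


def load_packaged_catalog() -> list[GeneRecord]:
    return load_catalog(packaged_catalog_path())


def summarize(records: list[GeneRecord]) -> CatalogSummary:
    """Census statistics: per-chromosome / per-family counts and descriptor ranges.

    Family membership is parsed from the AGNC gene name; unparsable
    names are flagged and excluded from family counts only.  Zero-exon
    records (the unplaced-loci convention) are excluded from the exon
    range so a placeholder never masquerades as a one-exon gene.
    """
    if not records:
        raise ValidationError("cannot summarize an empty catalog")
    per_chrom: dict[str, int] = {}
    per_family: dict[int, int] = {}
    unparsed: list[str] = []
    for rec in records:
        per_chrom[rec.chromosome] = per_chrom.get(rec.chromosome, 0) + 1
        parsed = parse_gene_name(rec.gene_name)
        if parsed is None:
            logger.warning("gene name %r does not parse as AGNC; excluded from family counts", rec.gene_name)
            unparsed.append(rec.gene_name)
        else:
            per_family[parsed[0]] = per_family.get(parsed[0], 0) + 1
    lengths = [r.protein_length for r in records]
    mws = [r.molecular_weight for r in records]
    pis = [r.isoelectric_point for r in records]
    exons = [r.exon_count for r in records if r.exon_count > 0]
    return CatalogSummary(
        n_loci=len(records),
        n_placed=sum(r.placed for r in records),
        per_chromosome_counts=dict(sorted(per_chrom.items())),
        per_family_counts=dict(sorted(per_family.items())),
        protein_length_range=(min(lengths), max(lengths)),
        mw_range=(min(mws), max(mws)),
        pi_range=(min(pis), max(pis)),
        exon_range=(min(exons), max(exons)) if exons else None,
        unparsed_gene_names=unparsed,
    )
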