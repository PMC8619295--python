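"""Homology-hit screening and AGNC-style family classification.

Candidate loci arrive as tabular BLASTP-like hits and survive a
coverage/identity/E-value screen.  Confirmed proteins are then
partitioned into families and subfamilies by pairwise global-alignment
identity against labeled references, following the gene-nomenclature
convention for aldehyde dehydrogenases: >40% identity to a previously
identified member places a protein in that family, >60% in that
subfamily, and a protein below 40% to everything opens a new family.

Assignment is greedy and anchored: proteins are processed in input
order, each compared against the references plus everything assigned
before it, with ties broken by lexicographic id so the outcome is
deterministic.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .alignment import global_identity
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

# Candidate screen thresholds (coverage and identity in percent).
MIN_QUERY_COVERAGE = 25.0
MIN_IDENTITY = 25.0
MAX_EVALUE = 1e-25

FAMILY_IDENTITY_THRESHOLD = 40.0
SUBFAMILY_IDENTITY_THRESHOLD = 60.0


@dataclass(frozen=True)
class HomologyHit:
    """One tabular homology hit (BLAST outfmt-6-like dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    query_coverage: float
    e_value: float

    def validate(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative E-value")
        if not (0 <= self.pct_identity <= 100):
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: identity outside [0, 100]")
        if not (0 <= self.query_coverage <= 100):
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: coverage outside [0, 100]")


@dataclass(frozen=True)
class FamilyAssignment:
    """Family/subfamily placement of one protein with its identity evidence."""

    protein_id: str
    family: int
    subfamily: str
    member_index: int | None = None
    evidence: float | None = None  # max % identity to the anchoring sequence


@dataclass(frozen=True)
class LabeledProtein:
    """A reference sequence with a known family/subfamily label."""

    protein_id: str
    sequence: str
    family: int
    subfamily: str


def filter_candidate_hits(
    hits: list[HomologyHit],
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_QUERY_COVERAGE,
    max_evalue: float = MAX_EVALUE,
) -> list[HomologyHit]:
    """Retain hits with coverage >= 25%, identity >= 25% and E-value <= 1e-25."""
    kept = []
    for hit in hits:
        hit.validate()
        passes_cov = hit.query_coverage >= min_coverage
        passes_ident = hit.pct_identity >= min_identity
        passes_e = hit.e_value <= max_evalue
        if passes_cov and passes_ident and passes_e:
            kept.append(hit)
        elif passes_cov and passes_ident:
            logger.info(
                "hit %s->%s excluded solely by E-value (%.3g > %.3g)",
                hit.query_id, hit.subject_id, hit.e_value, max_evalue,
            )
    return kept


def load_hits_tsv(path: str | Path) -> list[HomologyHit]:
    """Read a hit table with columns qseqid, sseqid, pident, qcovs, evalue."""
    df = pd.read_csv(path, sep="\t")
    required = ["qseqid", "sseqid", "pident", "qcovs", "evalue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return [
        HomologyHit(str(r.qseqid), str(r.sseqid), float(r.pident), float(r.qcovs), float(r.evalue))
        for r in df.itertuples(index=False)
    ]


def _next_subfamily_letter(used: set[str]) -> str:
    for letter in string.ascii_uppercase:
        if letter not in used:
            return letter
    raise ValidationError("subfamily letters exhausted (more than 26 subfamilies in one family)")


def assign_families(
    proteins: dict[str, str],
    references: list[LabeledProtein],
) -> list[FamilyAssignment]:
    """Greedy anchored family/subfamily assignment by global identity.

    Each protein (in input order) is compared against all references
    plus every previously assigned protein; the highest-identity anchor
    (ties broken by lexicographic id) decides: subfamily if >60%, family
    with a new subfamily letter if >40%, otherwise a brand-new family
    numbered one past the current maximum.
    """
    if not references:
        raise ValidationError("reference set must be non-empty")
    pool: list[LabeledProtein] = list(references)
    used_letters: dict[int, set[str]] = {}
    for ref in references:
        used_letters.setdefault(ref.family, set()).add(ref.subfamily)
    assignments: list[FamilyAssignment] = []
    for pid, seq in proteins.items():
        scored = sorted(
            ((global_identity(seq, anchor.sequence), anchor) for anchor in pool),
            key=lambda t: (-t[0], t[1].protein_id),
        )
        best_identity, best = scored[0]
        if best_identity > SUBFAMILY_IDENTITY_THRESHOLD:
            family, subfamily = best.family, best.subfamily
        elif best_identity > FAMILY_IDENTITY_THRESHOLD:
            family = best.family
            subfamily = _next_subfamily_letter(used_letters.setdefault(family, set()))
        else:
            family = max(used_letters) + 1 if used_letters else 1
            subfamily = "A"
        used_letters.setdefault(family, set()).add(subfamily)
        assignments.append(FamilyAssignment(pid, family, subfamily, evidence=best_identity))
        pool.append(LabeledProtein(pid, seq, family, subfamily))
    return assignments


def name_genes(assignments: list[FamilyAssignment], species_prefix: str) -> list[str]:
    """AGNC names <prefix>ALDH<family><subfamily><member>.

    Member indices already present on an assignment are preserved;
    missing ones are filled densely from 1 within each subfamily in
    input (catalog) order, skipping indices taken explicitly.
    """
    taken: dict[tuple[int, str], set[int]] = {}
    for a in assignments:
        if a.member_index is not None:
            taken.setdefault((a.family, a.subfamily), set()).add(a.member_index)
    names = []
    next_index: dict[tuple[int, str], int] = {}
    for a in assignments:
        key = (a.family, a.subfamily)
        if a.member_index is not None:
            member = a.member_index
        else:
            member = next_index.get(key, 1)
            while member in taken.setdefault(key, set()):
                member += 1
            taken[key].add(member)
            next_index[key] = member + 1
        names.append(f"{species_prefix}ALDH{a.family}{a.subfamily}{member}")
    return names


def assignments_to_frame(assignments: list[FamilyAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.protein_id, a.family, a.subfamily, a.member_index, a.evidence) for a in assignments],
        columns=["protein_id", "family", "subfamily", "member_index", "evidence"],
    )
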