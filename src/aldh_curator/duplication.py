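"""Gene-duplication labeling and tandem-cluster detection.

A gene pair is called duplicated when one optimal global alignment of
their coding sequences covers more than 70% of the longer gene and the
aligned region exceeds 70% identity (the 70/70 rule, both strict).
Calls are classified *tandem* when both genes sit on the same
chromosome, belong to the same family and are separated by less than
250 kb, and *dispersed* otherwise — the dispersed class covers both
inter-chromosomal pairs and same-chromosome pairs beyond the window,
the signature of segmental rather than local duplication.  Tandem
clusters are built by single-linkage chaining of same-family duplicated
genes along a chromosome with a per-gap threshold of 250 kb, which on
sparse gene sets is equivalent to a sliding window and is independent
of catalog row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .alignment import align_cds
from .catalog import GeneRecord
from .errors import ValidationError

COVERAGE_THRESHOLD = 70.0  # percent of the longer gene, strict
IDENTITY_THRESHOLD = 70.0  # percent over the aligned region, strict
TANDEM_WINDOW_BP = 250_000  # per-gap threshold, strict


@dataclass(frozen=True)
class DuplicationCall:
    """One gene pair passing the 70/70 duplicate rule."""

    gene_a: str
    gene_b: str
    coverage_of_longer: float
    identity: float
    mode: str  # tandem | dispersed | unplaced

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    member_loci: tuple[str, ...]
    max_gap_bp: int


def intergenic_gap(a: GeneRecord, b: GeneRecord) -> int | None:
    """Boundary-to-boundary distance between two placed same-chromosome genes.

    Overlapping spans give 0; different chromosomes or unplaced genes
    give None (an undefined-gap signal, not an exception).
    """
    if not a.placed or not b.placed or a.chromosome != b.chromosome:
        return None
    (a_lo, a_hi), (b_lo, b_hi) = a.span, b.span
    if a_lo > b_lo:
        a_lo, a_hi, b_lo, b_hi = b_lo, b_hi, a_lo, a_hi
    return max(0, b_lo - a_hi)


def _call_mode(a: GeneRecord, b: GeneRecord) -> str:
    if not a.placed or not b.placed:
        return "unplaced"
    gap = intergenic_gap(a, b)
    same_family = a.family is not None and a.family == b.family
    if gap is not None and gap < TANDEM_WINDOW_BP and same_family:
        return "tandem"
    return "dispersed"


def label_duplicates(cds: dict[str, str], catalog: list[GeneRecord]) -> list[DuplicationCall]:
    """Apply the 70/70 rule to every unordered CDS pair.

    CDS are keyed by locus id and every id must have a catalog record;
    self-pairs are never emitted and the output is independent of pair
    order.
    """
    by_locus = {rec.locus_id: rec for rec in catalog}
    orphans = sorted(set(cds) - set(by_locus))
    if orphans:
        raise ValidationError(f"CDS without catalog record: {', '.join(orphans)}")
    calls = []
    for locus_a, locus_b in combinations(sorted(cds), 2):
        stats = align_cds(cds[locus_a], cds[locus_b])
        if stats.coverage_of_longer_pct > COVERAGE_THRESHOLD and stats.identity_pct > IDENTITY_THRESHOLD:
            mode = _call_mode(by_locus[locus_a], by_locus[locus_b])
            calls.append(DuplicationCall(locus_a, locus_b, stats.coverage_of_longer_pct, stats.identity_pct, mode))
    return calls


def find_tandem_clusters(catalog: list[GeneRecord], duplicates: list[DuplicationCall]) -> list[TandemCluster]:
    """Single-linkage chaining of same-family duplicated genes within 250 kb gaps."""
    duplicated = {g for call in duplicates for g in (call.gene_a, call.gene_b)}
    placed = [r for r in catalog if r.placed and r.locus_id in duplicated and r.family is not None]
    clusters: list[TandemCluster] = []
    chromosomes = sorted({r.chromosome for r in placed})
    for chrom in chromosomes:
        on_chrom = sorted((r for r in placed if r.chromosome == chrom), key=lambda r: r.span[0])
        families = sorted({r.family for r in on_chrom})
        for family in families:
            genes = [r for r in on_chrom if r.family == family]
            chain: list[GeneRecord] = []
            gaps: list[int] = []
            def flush() -> None:
                if len(chain) >= 2:
                    clusters.append(TandemCluster(chrom, tuple(r.locus_id for r in chain), max(gaps)))
            for rec in genes:
                if chain:
                    gap = intergenic_gap(chain[-1], rec)
                    if gap is not None and gap < TANDEM_WINDOW_BP:
                        chain.append(rec)
                        gaps.append(gap)
                        continue
                    flush()
                chain, gaps = [rec], []
            flush()
    clusters.sort(key=lambda c: (c.chromosome, c.member_loci))
    return clusters


def duplication_rate(catalog: list[GeneRecord], calls: list[DuplicationCall]) -> dict[str, float]:
    """Fraction of loci in >=1 call, plus the cross-chromosome share of calls.

    The cross-chromosome share is reported both per call pair and per
    participating gene (a gene counts as cross-chromosome when all of
    its calls reach across chromosomes).
    """
    loci = {r.locus_id for r in catalog}
    by_locus = {r.locus_id: r for r in catalog}
    involved = {g for call in calls for g in (call.gene_a, call.gene_b)} & loci
    rate = 100.0 * len(involved) / len(loci) if loci else 0.0

    def cross(call: DuplicationCall) -> bool:
        a, b = by_locus.get(call.gene_a), by_locus.get(call.gene_b)
        return bool(a and b and a.placed and b.placed and a.chromosome != b.chromosome)

    cross_calls = [c for c in calls if cross(c)]
    pair_share = 100.0 * len(cross_calls) / len(calls) if calls else 0.0
    cross_only_genes = {
        g for g in involved
        if all(cross(c) for c in calls if g in (c.gene_a, c.gene_b))
    }
    gene_share = 100.0 * len(cross_only_genes) / len(involved) if involved else 0.0
    return {
        "rate_pct": rate,
        "n_duplicated_loci": float(len(involved)),
        "n_loci": float(len(loci)),
        "cross_chromosome_pair_share_pct": pair_share,
        "cross_chromosome_gene_share_pct": gene_share,
    }
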