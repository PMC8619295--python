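"""Expression support: EST screening, count normalization and MA analysis.

EST evidence is accepted under a stringent screen (identity > 95%,
query coverage > 25%, E-value < 1e-20, all strict).  Read counts from a
two-library comparison (pathogen-inoculated vs. control roots) are
normalized to counts per million (CPM); the between-condition contrast
is an MA representation — M the log2 ratio, A the mean log2 signal —
computed on pseudocounted CPM, with a gene flagged *enriched* in a
condition when its pseudocounted normalized ratio exceeds 3.5-fold in
that direction.  The upstream read mapping that produces the raw count
table (one read per hit, read identity > 99%) is outside this module;
its output table is the input here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

EST_MIN_IDENTITY = 95.0   # strict >
EST_MIN_COVERAGE = 25.0   # strict >
EST_MAX_EVALUE = 1e-20    # strict <
ENRICHMENT_FOLD = 3.5     # strict >
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class EstHit:
    gene_id: str
    est_id: str
    pct_identity: float
    query_coverage: float
    e_value: float
    library_tissue: str = ""
    library_condition: str = ""


@dataclass
class CountTable:
    """Genes x libraries count matrix, raw and (optionally) CPM-normalized."""

    gene_ids: list[str]
    libraries: list[str]
    raw_counts: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts)
        if self.raw_counts.shape != (len(self.gene_ids), len(self.libraries)):
            raise ValidationError("count matrix shape does not match gene/library labels")
        if (self.raw_counts < 0).any():
            raise ValidationError("negative counts")

    def column(self, library: str, normalized: bool = True) -> np.ndarray:
        if library not in self.libraries:
            raise SchemaError(f"library {library!r} not in table (have {self.libraries})")
        matrix = self.normalized if normalized else self.raw_counts
        if matrix is None:
            raise ValidationError("table not normalized yet; call normalize_counts first")
        return matrix[:, self.libraries.index(library)]


@dataclass(frozen=True)
class MaPoint:
    gene_id: str
    A: float
    M: float
    enriched_in: str  # condition label or "none"
    fold_ratio: float


def filter_est_hits(hits: list[EstHit]) -> list[EstHit]:
    """Strict EST-support screen: identity > 95, coverage > 25, E < 1e-20."""
    return [
        h for h in hits
        if h.pct_identity > EST_MIN_IDENTITY
        and h.query_coverage > EST_MIN_COVERAGE
        and h.e_value < EST_MAX_EVALUE
    ]


def est_support_tallies(hits: list[EstHit]) -> tuple[pd.Series, pd.Series]:
    """(per-gene, per-tissue) EST counts over an already-filtered hit list."""
    df = pd.DataFrame([(h.gene_id, h.library_tissue) for h in hits], columns=["gene_id", "tissue"])
    if df.empty:
        return pd.Series(dtype=int), pd.Series(dtype=int)
    return df["gene_id"].value_counts(), df["tissue"].value_counts()


def normalize_counts(table: CountTable) -> CountTable:
    """Counts-per-million per library; a zero-total library stays all-zero."""
    totals = table.raw_counts.sum(axis=0).astype(float)
    norm = np.zeros_like(table.raw_counts, dtype=float)
    for j, total in enumerate(totals):
        if total > 0:
            norm[:, j] = table.raw_counts[:, j] * 1e6 / total
        else:
            logger.warning("library %r has zero total counts; normalized column left at zero", table.libraries[j])
    return CountTable(table.gene_ids, table.libraries, table.raw_counts, norm)


def ma_analysis(
    table: CountTable,
    inoculated: str,
    control: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fold_threshold: float = ENRICHMENT_FOLD,
) -> list[MaPoint]:
    """MA points on pseudocounted CPM with a directional fold-enrichment flag."""
    x = table.column(inoculated) + pseudocount
    y = table.column(control) + pseudocount
    points = []
    for gene, xi, yi in zip(table.gene_ids, x, y):
        m = float(np.log2(xi / yi))
        a = float(0.5 * (np.log2(xi) + np.log2(yi)))
        ratio = float(xi / yi)
        if ratio > fold_threshold:
            flag = inoculated
        elif 1.0 / ratio > fold_threshold:
            flag = control
        else:
            flag = "none"
        points.append(MaPoint(gene, a, m, flag, ratio))
    return points


def condition_correlation(
    table: CountTable,
    library_a: str,
    library_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Pearson correlation of log2 pseudocounted CPM across genes."""
    if len(table.gene_ids) < 3:
        raise ValidationError("need at least 3 genes for a correlation")
    x = np.log2(table.column(library_a) + pseudocount)
    y = np.log2(table.column(library_b) + pseudocount)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValidationError("zero variance in a library; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def count_table_from_long(df: pd.DataFrame) -> CountTable:
    """Long-format (gene_id, library, count) frame -> CountTable."""
    required = {"gene_id", "library", "count"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"count table missing column(s): {', '.join(sorted(missing))}")
    wide = df.pivot_table(index="gene_id", columns="library", values="count", aggfunc="sum", fill_value=0)
    return CountTable(list(wide.index), list(wide.columns), wide.to_numpy())
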