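# Methods

`aldh_curator` re-implements, as a tested library, the analysis chain used
to curate a plant gene superfamily from a genome release: census of a
gene catalog, identity-threshold family classification and nomenclature,
duplication and tandem-cluster inference from genomic coordinates,
expression-support screening, and efficiency-corrected RT-qPCR
quantification. The worked system is the chickpea (*Cicer arietinum*)
aldehyde dehydrogenase (ALDH) superfamily, whose 27-locus catalog is
bundled as a TSV fixture; everything else the pipeline consumes is
produced by seeded synthetic generators with recorded ground truth.

## Catalog census

The catalog stores genomic coordinates 1-based inclusive exactly as
printed in the source table — minus-strand rows keep start > end — and
exposes a normalized `(low, high)` span for interval arithmetic, so
round-tripping a catalog through disk is field-identical while
positional analyses stay strand-agnostic. Unplaced loci (chromosome
`Un`, zero coordinates) are excluded from every positional computation
but included in family statistics. The bundled table prints 0 exons for
the four unplaced loci; the loader never rewrites source data, so the
summary simply excludes zero-exon records from the exon range (on the
fixture this yields (9, 21) across placed loci).

Family membership is parsed from the AGNC-style gene name: root `ALDH`,
integer family, one uppercase subfamily letter, member integer
(`CaALDH3H2` → family 3, subfamily H, member 2).

## Family classification

Classification follows the ALDH nomenclature convention: a protein
sharing >40% identity with a previously identified member joins that
family, >60% joins that subfamily, and ≤40% to everything opens a new
family. Identity is percent identical columns of one optimal global
(Needleman–Wunsch) alignment, denominator excluding terminal-gap
columns, `X` never a match. The scoring scheme is fixed in
`alignment.py`: BLOSUM62, gap of length L costs 10 + L, end gaps
penalized. Because co-optimal alignments can differ in identity, the
reported value is the maximum over co-optimal alignments (enumeration
capped at 64); this makes the statistic independent of traceback
tie-breaking and reproducible against an exhaustive enumeration oracle.

Assignment is greedy and anchored — proteins processed in input order,
compared against references plus everything assigned before, ties broken
by lexicographic id — because the nomenclature criteria are phrased
relative to previously identified sequences. Subfamily letters are
allocated alphabetically skipping letters already used in the family;
new families are numbered one past the current maximum. Re-running the
assignment on its own output reproduces the same partition.

Candidate screening accepts homology hits with query coverage ≥ 25%,
identity ≥ 25% and E-value ≤ 1e-25 (the E-value inequality reads in the
direction of significance; exclusions caused solely by E-value are
logged). Active-site screening compiles PROSITE-syntax patterns
(`x`, `[..]`, `{..}`, `(n)`/`(n,m)`, `<`/`>` anchors) to regular
expressions and reports leftmost non-overlapping 1-based inclusive
matches. The two bundled ALDH active-site motif strings are convenience
transcriptions; consult the PROSITE database for authoritative entries.

## Duplication and tandem clusters

A gene pair is a duplicate when one optimal global alignment of the two
CDS covers >70% of the longer gene and the aligned region exceeds 70%
identity (both strict). CDS alignment uses match +2 / mismatch −3, gap
open 5 / extend 2; coverage is the longer gene's residues inside the
terminal-gap-trimmed aligned region over its full length. Intergenic
gaps are boundary-to-boundary distances of normalized spans, clamped at
0 for overlaps and undefined across chromosomes or for unplaced genes.

Tandem clusters chain same-family duplicated genes along a chromosome by
single linkage with a per-gap threshold of 250 kb — on sparse gene sets
this is equivalent to the sliding-window formulation and is independent
of catalog row order. Calls that are not tandem are labeled *dispersed*
(covering both inter-chromosomal pairs and same-chromosome pairs beyond
the window), the signature of segmental rather than local duplication.
The duplication rate is the fraction of loci appearing in at least one
call; because "share of duplications on different chromosomes" is
ambiguous between pairs and genes, both shares are reported.

## Protein descriptors

Molecular weight is the sum of average residue masses plus one water
(kDa); ambiguous residues are rejected. The theoretical pI solves net
charge = 0 under Henderson–Hasselbalch over the termini and D, E, C, Y,
H, K, R with the Bjellqvist pKa set, including its residue-specific
terminal adjustments. The charge is strictly decreasing in pH, so
bisection on [0, 14] converges; the interval is refined to 1e-8 (well
within 60 iterations) rather than stopping at a charge tolerance,
because near-neutral sequences have a flat charge curve and a
charge-based stop would leave the pH imprecise. The returned pI always
satisfies |charge| < 1e-4. Catalog MW/pI values are treated as data, not
as oracles for these functions (the underlying sequences are not
printed); correctness is checked against independent mass-table and
grid-scan oracles and against a second published implementation.

## Expression support

EST evidence passes a strict screen (identity > 95%, coverage > 25%,
E-value < 1e-20). Read-count tables are normalized to counts per million
per library; the two-condition contrast is an MA representation computed
on CPM + 1 pseudocount, with a gene flagged enriched when the
pseudocounted ratio exceeds 3.5-fold in either direction, and the
between-condition agreement summarized as the Pearson correlation of
log2 pseudocounted CPM. CPM with a pseudocount is a deliberate minimal
choice — the provenance of such tables (read mapping at >99% identity,
one read counted per hit) is upstream of this module. No significance
test is attached to the enrichment flag; it is a descriptive ratio
threshold, not an inference.

## qPCR quantification

Cq values are the first crossing of baseline-subtracted fluorescence
through a fixed threshold (default 75 RFU), interpolated **linearly in
log fluorescence** between the bracketing cycles — exact for exponential
growth (a curve F(c) = 10·2^c crosses 75 at exactly log2(7.5) ≈ 2.907).

Amplification efficiency uses window-of-linearity regression: every
contiguous window of 3–5 cycles of log10 baseline-subtracted
fluorescence is fit, windows need R² ≥ 0.998 and a per-cycle factor of
at least 1.1, and among eligible windows the highest-placed one (maximal
mean log fluorescence; ties to more points, then higher R²) is chosen.
Two failure modes drove this selection rule: (i) the baseline estimated
from early cycles contains real signal, and the residual constant after
subtraction steepens log fluorescence just above the baseline, so
steepest-window selection overestimates the factor (≈2.15 for a true
1.98 in simulation); (ii) plateau noise is occasionally collinear enough
to pass the R² gate, which the minimum-factor floor rejects. The
highest-placed window sits at the top of the exponential phase where the
residual constant is negligible and plateau windows fail the gate; with
0.5% multiplicative curve noise the planted factor 1.98 is recovered to
±0.01 (mean over 10 curves). The per-cycle amplification factor is
10^slope; efficiency is factor − 1 (a perfect doubling has factor 2,
efficiency 1) — both are always reported because the literature
conflates the two conventions. Accepted estimates satisfy
1 < factor ≤ 2.2 and R² ≥ 0.998.

The 3′:5′ RNA-integrity ratio is factor^(Cq5 − Cq3); ratios < 1.5 pass.

geNorm stability: per reference j, M_j is the mean over partner
references k of the SD across samples of log2(q_j/q_k), with
q = factor^(minCq − Cq); the worst reference is removed iteratively
until two remain. The report carries the full-panel M values and the
selected pair's own M (the SD of the finalists' log ratio) — the latter
is the "stability of the chosen pair" figure usually quoted.

NRQ: per target, RQ = factor^(meanCq_cal − meanCq_s) against the
calibrator sample; NRQ is RQ divided by the geometric mean of the
reference RQs; results are rescaled so the calibrator sits at exactly 1.
Standard errors propagate in log2 space as
sqrt(SE_goi² + (1/R²)·Σ SE_ref²) over R references, with each group's
SE = (SD/√n)·log2(factor); calibrator-group uncertainty is not
separately propagated. Technical replicates collapse to mean ± SE
before comparison. The two-fold regulation flag is strict: up if
fold > 2, down if fold < 0.5, otherwise none (exactly 2.0 is none).

## Synthetic data: what it emulates and what it does not

The generators are seeded (`numpy` Generator; default seed 20211110)
and byte-reproducible. Their defaults define the study conditions used
throughout the tests:

* **Proteins** — per-family random ancestors of 300–550 residues
  (mirroring the real catalog's 134–759 span), substitution-only
  mutants with measured identity verified into guarded bands:
  within-subfamily ≥ 65%, within-family 45–58%, between families ≤ 30%
  (5-point margins around the 40/60 thresholds make classification
  deterministic; near-threshold behavior is tested with hand-built
  boundary cases). Rejection sampling retries a family up to 60 times.
* **Genomes** — tandem clusters planted at gaps of 2–240 kb (inside the
  250 kb window), dispersed pairs split across chromosomes, duplicate
  CDS identities verified into 75–95%, unrelated genes verified to stay
  clearly below the 70/70 rule; separate entities are laid out ≥ 400 kb
  apart so no accidental chaining occurs.
* **Counts** — negative-binomial (dispersion 0.3) over bivariate
  lognormal latent means. Counting noise attenuates the latent log
  correlation (≈0.90× at the default regime), so the generator probes
  the attenuation numerically with a fixed internal seed and inflates
  the latent correlation so the emitted log2 counts carry the requested
  value (planted 0.9 recovered as 0.89–0.91 across seeds at n = 200).
  Enriched genes get a planted 16-fold mean ratio at elevated base
  expression: with dispersion 0.3 the log2-ratio noise SD is ≈ 1.1, so
  a ratio must sit ≈ 2σ above the 3.5-fold flag to be reliably
  recovered; 16-fold provides that margin. A consequence of dispersion
  0.3 is a non-trivial false-positive rate of the 3.5-fold flag on
  unenriched genes (≈ 11% analytically) — the flag is descriptive, not
  a test.
* **qPCR** — curves F(c) = F0·factor^c·(1 + ε), ε ~ N(0, 0.005), with a
  plateau after cycle 32; F0 encodes planted folds (and per-sample
  reference noise at the planted stability SD) so the design holds at
  the Cq threshold; the Cq table is produced by the package's own Cq
  caller. Replicate Cq noise SD defaults to 0.15 cycles. With 6
  replicates per group and two references, a planted 4-fold induction
  is recovered with a typical error of ~7% (some seeds reach the 15%
  band edge — the expected precision at this noise level).

The generators emulate the *statistical structure* the methods operate
on, not the biology: substitution-only evolution (no indels or domain
shuffling), no GC/codon structure in CDS, no intron structure beyond a
span multiplier, no library-composition biases in counts, and ideal
single-amplicon PCR chemistry. Passing recovery tests therefore shows
the algorithms invert their own generative assumptions correctly — not
that real data satisfy those assumptions.

## Problem sizes and numerics

Tests and the acceptance script run desk-scale by design: 12–30 genes
for classification/duplication, 200 genes for counts, 10 curves per
efficiency estimate, 100 seeded panels for geNorm selection. Alignment
identity is validated against an exhaustive Gotoh traceback-enumeration
oracle on sequences of length ≤ 8, where enumeration is tractable.
Floating-point ties in window selection and reference ranking are broken
deterministically (documented orderings); all randomness flows from a
single seed per generator call.

## Known limitations

* The bundled PROSITE motif strings are best-effort transcriptions.
* The greedy anchored classifier is order-dependent near the 40/60
  thresholds by construction; the guard-banded generator avoids the
  region, and real borderline cases should be reviewed manually.
* `duplication_rate` treats any called pair as a duplication event;
  no Ka/Ks dating or synteny validation is attempted (precomputed
  synteny block tables can be joined onto calls for reporting only).
* NRQ error propagation ignores calibrator-mean uncertainty and
  inter-run calibration.
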