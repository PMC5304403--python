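# Methods

## Small-RNA preprocessing and two-phase annotation

Reads are cleaned in three steps: every read containing an `N` is removed;
the 3' sequencing adapter (default Illumina TruSeq small-RNA,
`TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC`) is trimmed; reads outside 18–33 nt
are discarded. Adapter detection finds the earliest position where a
prefix of the adapter matches through to the read's 3' end. For an overlap
of length *L* the mismatch budget is `min(2, L // 8)` and overlaps shorter
than 6 nt are never trimmed: a flat two-mismatch budget on short overlaps
would clip 1–2 nt from a few percent of clean reads by chance, which
silently shifts the length distribution of isomiRs. Trimming is iterated
to a fixed point, making it idempotent by construction. Quality strings
are carried in lockstep but never used for filtering.

Annotation is exact, not heuristic. Phase 1 enumerates every ungapped
sense-strand placement of the whole read inside each mature sequence and
keeps the placement minimising (mismatches, offset, reference order),
rejecting anything above 2 mismatches. Reads that fail phase 1 — typically
3'-extended isomiRs longer than every compatible reference — enter
phase 2, where the roles are swapped and a whole mature sequence is placed
inside the read under the same rule. Multi-mapping ties (e.g. family
members sharing a seed) are resolved by the deterministic tie-break and
logged at debug level; counts plus the unassigned tally always equal the
input read number. The test suite checks the annotator against an
independent brute-force enumeration on hundreds of random instances.

## Seed sites, mutagenesis, sponge design

Site classes follow the canonical definitions: 7mer-m8 is the reverse
complement of miRNA positions 2–8 on the UTR sense strand; 8mer adds an
`A` opposite position 1; 7mer-A1 matches positions 2–7 plus that `A`.
No G:U wobble is allowed, `N` never matches, coordinates are 0-based
half-open, and a 7mer-A1 wholly contained in a reported 8mer is
suppressed so one biological site is reported once. The scanner is
checked against a naive all-window comparison.

Site mutagenesis substitutes exactly *n* bases (default 3) inside the
site window by the transversion of the current base (A↔C, G↔T), which
always breaks Watson–Crick pairing; the position subset is advanced
deterministically until a rescan confirms no site overlaps the window,
so the knockout is guaranteed.

Sponge constructs are `repeats` (default 7) tandem copies of the reverse
complement of the full mature sequence with the four bases pairing miRNA
positions 9–12 transverted, joined by a spacer (default `CATT`). The
central bulge prevents Ago2-mediated slicing while perfect seed pairing
retains binding. Pairing positions 1–8 complementary and 9–12
non-complementary is an enforced invariant, and the designer verifies by
rescanning that the construct contains exactly one seed site per repeat,
advancing through a fixed spacer list if a junction ever creates a
spurious site. The exact substituted bases and spacer are this package's
deterministic choices; any non-seed-forming alternative would serve.

## Anticorrelation statistic

Per-target Pearson correlations with the miRNA are computed across all
age × replicate samples by default; a per-age-mean layout (5 points) is
available via `AnticorrConfig.sample_layout` since either is a defensible
reading of the design. The null pools `B` = 1000 draws of |T| genes,
sampled without replacement within a draw, from the non-target pool
(gene resampling, rather than sample or value resampling, matches the
question "do *targets* correlate more negatively than comparable genes?").

The KS p-value is a deliberate numerical choice: pooled bootstrap values
re-use a finite gene pool, so they are far from independent and the raw
pooled length would be an anti-conservative sample size. `ks_compare`
therefore takes an effective null size — the pipeline passes the distinct
non-target gene count *P* — and evaluates the classical asymptotic
two-sample formula at `ne = |T|·P/(|T|+P)` (Kolmogorov distribution for
two-sided; `exp(-2·ne·D²)` for the one-sided "targets-less" alternative).
The default is two-sided; the one-sided variant is available by flag.
Under repeated null simulation (no coupling) the rejection rate at
α = 0.05 is calibrated within Monte-Carlo error, and at the study
conditions (coupling 1, noise 0.3, 200 targets, 25 samples) power
exceeds 0.9 — both are asserted in the acceptance suite.

## Enrichment consensus

For a cluster of size *n* in a universe of size *N* and a target set of
size *K* with overlap *k*, three one-sided overrepresentation p-values
are computed: binomial (*k* successes in *n* draws at rate *K/N*), exact
hypergeometric upper tail, and one-sided Fisher (identical to the
hypergeometric tail; the identity is asserted as a cross-check rather
than collapsed). Each test's p-values are Hochberg-adjusted across
miRNAs (statsmodels' step-up implementation, verified in tests against a
hand-executed pass), and a miRNA is called only when all three adjusted
values fall below α = 0.05. Requiring the conjunction can only reduce
the family-wise error of the individually FWER-controlling adjustments;
the null calibration is checked by simulation.

## DEG concordance typing

Direction is the sign of `log2FC`; a gene with a zero fold change in
either contrast has no direction and is excluded with a warning rather
than guessed. Percentages are rounded to the nearest integer. The χ² test
of independence on the 2×2 sign table is computed without Yates
correction (the intersection sizes here make the correction both
unnecessary and non-standard for effect detection); if any expected count
falls below 5 the exact Fisher p is substituted and flagged.
`total_override` lets a caller use an externally printed intersection
total as the percentage denominator while the internally classified count
is always reported alongside — printed totals and classifiable counts can
legitimately differ by unclassifiable edge cases. Set-overlap tests
report the two-sided Fisher p with the sample odds ratio.

## Synthetic-data generator

The generator emulates the study design, not the biology: 5 age groups
(3–27 weeks) × 5 replicates; an RPKM-like nonnegative matrix with
multiplicative log-normal noise (σ = 0.3 on the natural-log scale,
matching positivity of RPKM); a miRNA whose group means interpolate
geometrically to an old/young ratio of 15 (exact when σ = 0); target
genes repressed by `coupling` (log2 units per SD of log2 miRNA level,
default 1); 2000 genes with 200 targets as a desk-scale transcriptome.
Small-RNA reads are a mature sequence with a 3' isomiR length shift
(default mostly 0, ±1–2 nt), the full adapter, substitution errors and
`N`s at 0.1% per base, constant Phred 40 qualities. DEG tables draw
|log2FC| from max(0.1, |N(1, 0.25)|) so signs are unambiguous, with
sub-threshold p/FDR values — they model already-filtered DEG lists.
A single seeded `numpy` generator drives all draws in a fixed order, so
identical configurations give byte-identical files.

What the generator does **not** emulate: count-based sampling noise
(negative binomial), gene–gene correlation structure, sequencing-quality
decay along reads, 5' isomiRs, ligation bias, batch effects, or
mapping ambiguity to a genome. Passing tests therefore certify the
*procedures* — exact annotation, calibrated statistics, exact typing —
under the assumed data structure, not performance on any real library.

## Problem sizes and numerical conventions

Simulation-heavy checks use 2000 genes × 25 samples with B = 1000
bootstrap draws, 500 replicates for null calibrations, and 100–300
replicates for power and script-level rates — sizes chosen to estimate
the rates to ~1–2% Monte-Carlo error. Degenerate inputs error loudly
(`InputError`/`ConfigError`) rather than returning NaN: zero-variance
correlations, empty universes or references, sites outside a UTR.
Rounding appears only at the reporting layer; internal computation stays
in double precision. All file formats are plain text (FASTA, FASTQ
Phred+33 with U→T normalisation recorded on load, tab-separated tables
with a header row, JSON with a provenance block carrying the package
version, configuration hash and seed).

## Known limitations

- The annotator is exhaustive and pure Python: exact and fast for
  miRNA-scale references (hundreds of ~22-nt sequences), not a genome
  mapper.
- The per-age-mean correlation layout leaves only 5 points per
  correlation; with few ages the KS comparison loses resolution.
- The bootstrap-KS p-value relies on the asymptotic formula; below ~20
  targets or non-target genes its calibration degrades.
- The enrichment consensus controls FWER per test family; it is not an
  FDR procedure, and no alternative corrections are provided.
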