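# Methods

This note documents the models and procedures editkit implements, the
parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer should know.

## Read model and preprocessing

A sequenced molecule is modelled as: mature miRNA sequence → optional
A→G flips at edited positions (independent across reads) → uniform
per-base substitution error → optional 2-base random non-templated 3′
tail → 3′ sequencing adaptor → truncation to a fixed machine read
length.  Cleaning applies four rules in order:

1. **Quality gate** — drop a read when *more than*
   `max_low_quality_positions` (3) bases are *strictly below*
   `quality_threshold` (phred 20).  Exactly three low positions is kept;
   a base at exactly phred 20 never counts as low.
2. **Adaptor removal** — the longest read suffix matching a prefix of
   the 3′ adaptor is removed, requiring ≥ 8 nt of overlap and tolerating
   one mismatch per 8 nt of overlap; a fully contained adaptor removes
   everything from its start onward.  The matching rule is ours (the
   analysis being reproduced does not name its trimmer); it is
   deterministic and oracle-tested against a brute-force scan.  Reads
   with no acceptable match are flagged and passed on — the length gate
   then removes them if they are still machine-length.
3. **Length gate** — keep inserts of 15–28 nt *inclusive* (the removal
   conditions are strict inequalities, `<15` and `>28`).
4. **3′ trim** — remove the final 2 bases, which carry non-templated
   modifications; applied last, immediately before alignment.

Phred encoding is fixed to offset 33 (Sanger/Illumina 1.8+).  Read
qualities are capped at phred 60 by the read invariant.

## Alignment and tallies

Reads are scanned against every admissible offset of every mature
reference on the sense strand (mature references are strand-resolved, so
no antisense search).  A candidate hit has at most `max_mismatches` (1)
mismatches, each carrying phred ≥ `mismatch_quality_min` (30).  The hit
with fewest mismatches wins; ties across distinct (reference, offset)
locations make the read *ambiguous*, and ambiguous reads are excluded
from both tallies and expression counts to avoid double counting.
Offsets up to `max_five_prime_offset` (3) tolerate 5′ isomiR wobble.
This replaces a genome-scale aligner plus miRNA projection: at desk
scale the per-miRNA position space is identical, and the mismatch policy
is equivalence-tested against an exhaustive Hamming-distance oracle.

Tallies count only bases with phred ≥ 30 — they contribute neither to
base counts nor to coverage below that.  The published rule states the
phred-30 filter for alignment mismatches; extending it to all tallied
bases is the conservative reading that makes the binomial test's
error-rate null (0.1% ≈ phred 30) match its own count denominator.  The
consequence is that coverage is the number of high-confidence
observations, not the raw read depth.

## Editing-site calling

For each position and each alternate base with n_alt > 0, the p-value is
the upper tail P(X ≥ n_alt) for X ~ Binomial(coverage, 0.001).  The test
is one-sided (editing can only inflate the mismatch count) and each
alternate base is tested against the *full* 0.1% error rate rather than
a third of it, which is conservative.  Multiple testing is corrected by
Bonferroni over every (position × alternate) test performed in the
sample (configurable: off / Bonferroni / Benjamini–Hochberg).  A site
with coverage below `nd_min_reads` (10) is reported **ND** regardless of
its p-value.  The editing level is 100·n_alt/(n_ref+n_alt); other
alternate bases are excluded from the denominator, matching the Sanger
peak-ratio definition G/(A+G).

The p-value floor: below double-precision underflow the caller returns
the dominant log-space term (never exactly zero), so downstream
Bonferroni multiplication and ordering remain well defined.

Seed annotation uses mature positions 2–8 (1-based, configurable); the
seed region has no universally fixed bounds and 2–8 is the common
definition.  Cross-sample comparison keys sites by (miRNA, position,
alternate) and flags a site *enzyme-specific* when it is significant in
the active-enzyme sample but not in the catalytically dead control.
Amplicon (precursor) mode reuses the same caller on a precursor
reference and labels positions relative to a user-supplied anchor, the
anchor base being +1 and the base before it −1, with no position zero.
The nucleotide opposing a site on the precursor stem is not computed —
that requires secondary-structure prediction, which is out of scope.

## Expression analysis

**Normalization** is trimmed mean of M-values: genes with a zero in
either sample are excluded; M (per-gene log2 ratio to the reference
sample, library-scaled) is trimmed by rank at 30% each side and A (mean
log2 abundance) at 5% each side; the surviving M-values are combined
with inverse delta-method-variance weights; factors are rescaled to unit
geometric mean.  The reference sample is the one whose upper-quartile
library-scaled count is closest to the across-sample mean.  Factors
agree with `edgeR::calcNormFactors(method="TMM")` to seven digits (a
unit test runs edgeR through Rscript as an independent cross-check).
Normalized counts are rescaled to the mean effective library size, so
they remain on a reads-like scale, and normalizing twice returns factors
of one.

A note on what trimming stabilizes: with genuine expression changes in
the contrast, the raw TMM factor legitimately moves (the changed genes
inflate the raw library total, and the factor compensates).  The
invariant quantity is the *effective* library ratio — total × factor —
which stays within 2% under 5% planted 4-fold changes; tests and the
acceptance script measure that quantity.

**Difference test**: the exact conditional test of equal Poisson rates.
Given n = a + b, under the null a ~ Binomial(n, E_a/(E_a+E_b)) with
exposures E taken from raw column totals, or equal exposures for a table
that is already normalized (normalization has put the samples on a
common scale; residual total differences are composition, not depth —
using totals there would bias every null gene).  Two-sidedness is by
minimum-likelihood summation: all outcomes whose pmf is ≤ the observed
pmf (with a 1e-7 relative tie guard) are summed.  a + b = 0 gives p = 1
by convention.  Bonferroni divides by the number of miRNAs with
a + b > 0 in the contrast.

Selection mirrors the published rules: sum of normalized counts
*strictly greater than* 200; |log2[(A+1)/(B+1)]| ≥ 0.5; the highly
expressed subset keeps sums ≥ 10,000 *inclusive*; and the reversal
filter keeps selected miRNAs whose fold-change in the knockdown contrast
has strictly the opposite sign, with no magnitude threshold on the
second contrast.

## Auxiliary statistics

Microarray probes carry replicate log2 ratios (three independent
experiments in the reproduced design).  Each probe gets a two-sided
one-sample t-test against zero, BH-FDR across probes (cutoff 0.2), and
an effect filter |mean log2| ≥ 0.5, boundary inclusive.  With three
replicates the t-test has two degrees of freedom; simulation at the
reproduced design's noise level (SD 0.2, |log2| = 1 effects) gives mean
recall ≈ 0.68 with realized false-discovery proportion ≈ 0 — the
procedure is specific but not powerful at n = 3, which is worth knowing
before trusting a non-selection.  Array normalization is upstream of
this module; it consumes already-normalized ratios.

2^−ΔΔCT consumes final Ct values (pre-amplification is not modelled):
ΔCt = target − endogenous control per sample, ΔΔCt against a calibrator
that maps to 1.  Sanger editing is 100·G/(A+G) peak areas; chromatogram
files themselves are not parsed — peak areas arrive as numbers.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
Poisson read counts per miRNA (chi-square goodness-of-fit tested),
independent per-read editing at planted fractions, uniform substitution
error across the three alternates, a 2-base random 3′ tail with
probability 0.5, adaptor-flanked fixed-length machine reads, and
qualities with a configurable low-quality fraction placed so that
mismatch bases fall on both sides of the phred-30 gate.  Quality and
error are drawn *independently*, so quality scores carry no information
about true error — real base callers are better than that, which makes
the synthetic setting conservative for the quality-gated caller.

Not emulated: PCR duplicates, indels, ligation bias, quality-by-cycle
profiles, molecule-level linkage between editing events, and SNP
contamination.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real libraries.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen so the whole suite
completes in minutes on one CPU: type-I control uses 100 seeded null
runs of 200 miRNAs at coverage 1,000; level recovery uses 100 runs of
planted 1/5/20/70% sites at coverage 2,000; oracle equivalence uses
1,000 random cases (a + b ≤ 5,000 for the Poisson test, n ≤ 10⁴ for the
binomial tail) at 10⁻⁹ relative tolerance, ignoring values below 10⁻³⁰⁰
where doubles denormalize; the end-to-end run uses 10 miRNAs at ~1,000
reads each.  Tallies for the caller simulations are drawn directly from
the binomial generative model; the read-level generator is exercised by
the end-to-end run and its own unit tests.

## Known limitations

- The published analysis aligned to the whole genome and projected onto
  miRNA annotation; editkit aligns to a mature-reference FASTA.  Reads
  from unannotated loci that would cross-map genome-wide are invisible
  here.
- Multi-mapping reads are dropped rather than fractionally assigned.
- The expression model is pure Poisson; biological replicates with
  overdispersion need a negative-binomial framework, which is out of
  scope.
- One row of the bundled published fold-change table (and the
  knockdown-contrast cells of two others) cannot be reproduced from its
  own printed counts; the validator asserts these cells as inconsistent
  rather than skipping them, and they are excluded from the
  4-decimal-place reproduction check.
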