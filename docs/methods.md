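# Methods

## Species classification by dual-genome alignment fidelity

Each fragment is aligned to both references; the best alignment per genome
is the minimum `NM` (edit distance) over all reported records, secondary
alignments included, because "fidelity" here means base mismatches rather
than mapping quality. Paired-end data are classified at **fragment level**:
mate `NM` values are summed, and a genome counts as aligning the fragment
only if both mates map there. This is the conservative reading of
paired-read processing; classifying mates independently would let a
single-mate alignment in one genome outvote a full pair in the other. If a
record lacks `NM`, the mismatch count is recovered from the `MD` tag;
records with neither are a hard error — guessing a mismatch count would
silently corrupt the partition.

Ties go to an *ambiguous* class that downstream analyses exclude. Reads
aligning in neither genome form an explicit *unaligned* class, and reported
fractions are over all input reads; published three-class tables are
recovered exactly when the unaligned class is empty, while keeping the
denominator auditable otherwise.

Invariants: the four classes partition the input; swapping the two input
SAMs swaps the human and mouse counts and leaves ambiguous/unaligned
unchanged; with identical references and error-free reads every aligned
fragment is ambiguous.

## Gene counting and normalization

A gene model is the union of its exons over all supplied GTF sources,
merged into disjoint intervals (internal coordinates are 0-based half-open;
GTF and SAM conventions are converted at the boundary). A mate counts
toward a gene only when its aligned interval is completely contained in a
single merged exon; a fragment is ascribed to a gene when all its mates are
contained in exons of that same gene. Fragments contained in exons of more
than one gene are discarded and tallied as *ambiguous-assignment* —
double-counting would inflate overlapping loci — and everything else
unassignable is tallied as *unassigned*, so assigned + ambiguous +
unassigned equals the input fragment count. Counting is unstranded (the
library chemistry emulated is unstranded).

CPM divides a gene's count by the library total in millions. The library
total defaults to the number of species-classified reads of the sample, not
the assigned-count sum, so genes' normalized values do not change when
unrelated genes gain or lose assignments.

## Orthologue joint analysis

A strictly 1:1 orthologue table maps the two gene universes onto common
rows; any gene appearing more than once on either side is dropped entirely
(with a count), because a many-to-many pair has no unambiguous joint
expression value. Each xenograft contributes a human (`-H`) and a murine
(`-M`) pseudo-sample. The default transform before correlation and
clustering is log2(CPM + 1); raw CPM is available since correlations on
the two scales answer different questions (log compresses the dynamic range
that a handful of very high expressors would otherwise dominate).

Clustering is correlation-of-correlations: Pearson correlation between all
pseudo-sample columns, Euclidean distance between rows of that correlation
matrix, then agglomerative clustering (average linkage by default —
complete and single are available; the choice is a convention, not a
result). Dendrograms are exported as Newick with branch lengths equal to
merge-height differences.

## Differential expression

Rather than depending on a full edgeR-style GLM engine, differential
expression is a self-contained equivalent with the same statistical
contract:

1. **Normalization.** Samples are put on a common scale by median-of-ratios
   size factors (ratios against the per-gene geometric mean over genes
   expressed everywhere, factors scaled to geometric mean 1; column totals
   are the fallback when too few genes qualify). Plain library totals are
   available as an option, but when expression changes concentrate in one
   direction they carry a composition bias that shifts every null gene —
   measured on planted-change simulations, this inflates the false
   discovery proportion several-fold, which is why median-of-ratios is the
   default for testing. CPM reporting (fold changes) still uses library
   totals.
2. **Dispersion.** Per gene, a method-of-moments estimate pooled within
   groups, $\hat\phi = (s^2 - \bar x)/\bar x^2$, shrunk toward the common
   dispersion with weight `prior_df / (prior_df + residual_df)`,
   `prior_df = 20` by default. The common value is the df-weighted **mean**
   of raw estimates: the raw estimator's sampling distribution is
   right-skewed, so the median is biased low, and an underestimated common
   dispersion makes every test anti-conservative. Estimates are floored at
   zero. These choices were calibrated against the estimator's stated
   contract — near-uniform null p-values — on null NB simulations.
3. **Test.** Group sums of the normalized pseudo-counts are conditioned on
   their total; under a common-dispersion NB model the conditional law of
   one group's sum is free of the mean, and the two-sided p-value sums the
   probability of every split no more probable than the observed one
   (minimum-likelihood convention). At dispersion zero this is exactly the
   conditional binomial (Poisson) test, which is how the implementation is
   validated against an enumeration oracle.
4. **Multiplicity.** Benjamini–Hochberg step-up (via statsmodels); genes at
   FDR < 0.05 are flagged. BH output is order-preserving on sorted inputs
   but not idempotent; it is applied once, to the raw p-values.

Log fold changes are log2 of group-mean CPM ratios with a 0.5 offset on
both means to keep zero-count genes finite.

Measured operating characteristics (seeded simulations in the test suite):
with 5 samples per group, 2000 genes, dispersion 0.1 and a 6-fold change
planted in 5% of genes, sensitivity is ≥ 0.5 (in practice ~1.0) at an
observed false discovery proportion ≤ 0.10; under the null the flagged
fraction is ~0 and the p-value distribution is uniform within KS ≤ 0.05.

## Gene-set enrichment

For a set with $K$ of $N$ universe genes and $n$ DE genes observed to hit
the set $k$ times, over/under-representation tails come from the Wallenius
non-central hypergeometric distribution with odds equal to the mean bias
weight of in-set genes over out-of-set genes (scipy's implementation). With
no or equal weights the odds are exactly 1 and the code routes to the
central hypergeometric, which both makes the Fisher reduction bitwise exact
and avoids the numerical integration. The sequential weighted-sampling
Monte-Carlo oracle for the biased case lives in the tests. Bias weights
default to uniform; gene length or mean expression can be supplied — a
fitted probability-weighting function is out of scope.

## Variant allele tallies

At each specified locus, every aligned read covering the position
contributes its base (located through the CIGAR via aligned pairs;
deletions and skips at the position are ignored) to a forward/reverse ×
WT/mut table. No base- or mapping-quality filter is applied by default (a
minimum base quality is available). Bases matching neither allele are
excluded from the percentage denominator and reported separately.
Overlapping mates are counted independently, matching per-strand transcript
tallies. Percentages are rounded **half-even** to integers — the convention
that reproduces all arithmetic-consistent published tally rows (a half-up
rule fails on 62.5% → 62).

## Growth kinetics

Exponential growth is fitted as a least-squares line of ln V against t
(needs ≥ 3 points, all volumes positive): k is the slope, V0 the
exponentiated intercept, Td = ln 2 / k, and R² is computed on the log scale
for consistency with the linearized model. A perfectly flat series has
R² = 0 by convention (no variance to explain). Series with R² < 0.5
(strict) or k ≤ 0 are non-exponential; shrinking tumors get Td = NaN with
the negative slope preserved. The fit is scale-equivariant in volume and
invariant to time shifts.

## qPCR ratios

Expression ratios between samples are N0 estimates normalized to GAPDH in
each sample. Undetectable target transcripts are replaced by a caller-
supplied floor (the minimal observed expression) and flagged with the
substitution direction; when both sides are undetectable the ratio is
flagged indeterminate. Undetectable GAPDH is an error — the normalizer
cannot be imputed.

## The synthetic-data generator

The generator defines the conditions under which the pipeline's claims are
tested:

- **References.** Orthologous transcript pairs differ by independent
  per-base substitutions (never back to the original base) at a
  configurable rate, default 0.12 — the order of typical human–mouse exonic
  divergence. Genes are single-exon and unspliced so that containment
  counting and pileups are exactly checkable; splicing is the upstream
  aligner's problem and out of scope. No indels: the classifier compares
  mismatch counts only.
- **Reads.** 50 bp paired-end by default (the emulated library design);
  species per fragment from the configured mixture, uniform gene and start
  position; each base flips to a different base independently with the
  error rate (default 0.01). Paired fragments span `read_length` to
  `min(6*read_length, transcript)` bases, so inserts average ~175 bp at
  default length; both mates come from one fragment and the truth label
  attaches to the fragment.
- **Alignments.** Because orthologues share coordinates, the simulator
  writes both genomes' alignments directly with `NM` equal to the true
  Hamming distance — it bypasses an aligner, which is exactly what makes
  NM-correctness brute-force checkable. An optional maximum-mismatch cutoff
  emits distant alignments as unmapped records (by default everything is
  reported, leaving filtering decisions observable downstream).
- **Counts and growth.** NB counts with log-uniform gene means, a planted
  fold change in a configurable gene fraction (one-directional, as a real
  stroma-loss contrast is), and exponential growth series with log-normal
  noise.

Identical configuration and seed give byte-identical outputs.

What the generator does *not* emulate — splicing, indels, quality-score
structure, GC and positional bias, duplicates, multi-mapping across gene
families — bounds what passing tests show: they validate the logic and the
statistics of the pipeline under its own model, not aligner behavior on
real genomes. In particular, real-data misclassification rates depend on
local homology structure that uniform divergence does not capture; the
simulated bound (≲ 0.01% of pure-human reads flagged mouse at 12%
divergence, 1% error, well under the 0.2% contract) is a best case.

## Problem sizes

Simulation-based checks use sizes chosen to make their statistical targets
well-separated from their thresholds: 50,000 fragments for the
misclassification bound, 2000 genes × 5 samples per group for DE
calibration, 10⁶ draws for the Wallenius Monte-Carlo oracle, 100 replicates
for doubling-time recovery. Exhaustive oracles (Fisher tables with margins
≤ 12, allele-fraction quadruples with total ≤ 50) enumerate their full
domain.
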