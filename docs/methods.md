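# Methods

## The contact model

A microdissected nucleolus captures the DNA in and immediately around the
nucleolar volume. At bin resolution this is a binary observation: bin *b* is
either present in cell *j*'s calls or it is not. The cohort-level summary is
the contact frequency CF(b), the proportion of cells whose calls contain *b*;
a bin is a cohort NAD when CF(b) strictly exceeds a threshold (default 0.20).
The strict inequality matters at small cohort sizes: with 53 cells the
smallest passing count is 11 (11/53 ≈ 0.2075 > 0.20, while 10/53 ≈ 0.189
fails). All coverage fractions are bp-weighted (terminal bins of a chromosome
may be shorter than the nominal bin size), and coordinates are 0-based
half-open throughout; 1-based inputs must be converted at the I/O boundary.

## False-positive calibration

Microdissection inevitably captures sequence above and below the nucleolus,
so each cell's calls contain non-NAD bins. Modelling the presence of a given
non-NAD bin in one cell as Bernoulli(p), its recurrence count across *n*
independent cells is Binomial(n, p), and the probability it passes the CF
cutoff is the tail P(X ≥ k_min) with k_min = min{k : k/n > threshold}.
Multiplying by the number of genome bins gives the expected number of false
NAD calls. `binomial_tail` delegates to the regularized incomplete beta
function (scipy), stable far below 1e−12; `implied_contamination` inverts the
model by bisection (Brent) to recover the *p* consistent with a stated
per-bin rate — useful because published worked examples typically print the
rate, not *p*. For a per-bin rate of 1.44 × 10⁻⁶ at n = 53 and threshold
0.20, the implied p is ≈ 0.034 and a 27,904-bin genome yields 0.04 expected
false calls.

## The synthetic cohort generator

The generator emulates the statistical structure the method assumes, at the
unit where the analysis operates (the binary bin call); it deliberately does
not simulate reads, amplification bias, or the upstream island caller.

**Genome.** Default is a 21-chromosome scaled-down mouse-like karyotype
(autosomes decreasing in size, then X and Y; ~2,850 bins of 100 kb), chosen so
that full-cohort simulations run in seconds. Chromosomes 12, 16, 18 and 19
are marked as rDNA-bearing.

**Truth.** NAD bins form contiguous blocks with geometric lengths (mean 5
bins ≈ 0.5 Mb); gap lengths are geometric with the mean set so the expected
NAD fraction is 0.25 of the genome, in line with population-level NAD
coverage estimates. Each block draws a base contact probability uniformly
from [0.25, 0.95]; bins on rDNA chromosomes are multiplied by
`rdna_contact_boost` (default 2, clipped at 1), reflecting the higher
nucleolar affinity of rRNA-gene-bearing chromosomes. With two populations
(default), per-chromosome weight vectors plant the mutually exclusive
pattern observed between stem-cell subpopulations: half of the rDNA
chromosomes contact preferentially in population 1, the other half in
population 2.

**Capture.** Per cell, true contacts are Bernoulli draws at the
population-weighted probabilities, rescaled so the expected true-contact
content is (1 − contamination) × recovery × n_bins with recovery 0.15 and
contamination 1/3 — i.e. ~10% of the genome as real contacts and ~5% as
noise, matching the observed ~15% per-cell recovery of which a third is
estimated to be non-NAD debris. Probability-1 contacts are treated as
structural and never thinned by the rescaling; this keeps the noise-free
limit exact (contamination 0 and degenerate probabilities reproduce the
truth bit-for-bit through the full CF → calling path). Contamination is an
exact per-cell count of uniformly drawn non-NAD bins — uniform because only
the aggregate one-third figure is known, making uniformity the
maximum-entropy choice; the exact count keeps the one-third proportion tight
per cell. One independent RNG stream is spawned per cell from the single
cohort seed.

**Alleles.** In hybrid mode each NAD bin receives a regime: bi-allelic (both
haplotypes contact), random-mono (86% by default — the contacted allele is
chosen per cell by a fair coin), or parent-fixed (1% of mono bins). This
encodes the finding that mono-allelic contacts are generally *not*
parent-specific: the same bin contacts via the maternal allele in one cell
and the paternal in another. Contaminant bins are assigned to a random
single allele.

**What passing tests do not show.** The generator produces exchangeable
cells, uniform contamination, and block-wise constant contact probabilities.
Real cohorts have per-cell quality variation, coverage-correlated noise,
mappability structure, and copy-number effects; recovery rates and
false-positive calibration on synthetic cohorts therefore validate the
*statistics*, not the upstream calling.

## Allelic classification granularities

Mono- vs bi-allelic contact is fundamentally a per-nucleolus property: in a
single cell a bin either contacted one haplotype or both. Because the
contacted allele of a mono-allelic NAD switches between cells, aggregating
to cohort CF washes the signal out — a random-mono bin shows CF ≈ p/2 on
*both* alleles. The package therefore reports both granularities:

- `classify_allelic_per_cell`: per-cell proportions of mono/bi-allelic
  contacted bins (the statistic behind the ~86% mono-allelic share);
- `classify_allelic`: the cohort-level CF-pair rule (both allele CFs above
  the NAD threshold → bi-allelic; exactly one → mono), an interpretation
  suited to cohort-level NAD sets, with the per-allele threshold reusing the
  cohort NAD threshold (0.20) as a named, configurable parameter;
- `parent_specific`: the stringent cohort-level rule (CF > 0.25 on one
  allele and < 0.10 on the other), which correctly isolates parent-fixed
  NADs precisely because random-mono bins sit near (p/2, p/2).

Mono fractions are additionally reported per bin and per merged segment (a
segment counts as bi-allelic if any of its bins is).

## Cohort structure statistics

**Yule's Q** for a cell pair is (ad − bc)/(ad + bc) over the 2×2 concordance
counts of their binary profiles. Pairs with ad + bc = 0 are reported missing,
not 0, to avoid biasing similarity distributions.

**Autocorrelation** is computed per cell within chromosomes only (lags never
cross a chromosome boundary — such lags have no genomic meaning), as the
Pearson correlation of the profile with its lag-shifted self at lags 1–50,
then combined across chromosomes with (bins − lag) weights (a simple mean is
available). Constant chromosomes are skipped. The decay is summarized by a
nonlinear least-squares fit of a·e^(−bx), initialized from a log-linear
regression on the positive ACF values and with b constrained non-negative;
nonlinear (rather than pure log-linear) because ACF values can be ≤ 0 where
logarithms are undefined. Noiseless curves are recovered to machine-level
accuracy (the test fixtures use published decay parameters a = 0.74,
b = 0.23 and a = 0.64, b = 0.34).

**Coverage-matched randomization** re-draws each cell's contacted bins
uniformly without replacement, preserving the per-cell contacted-bin count
exactly; it abolishes both the rDNA-class CF excess and the spatial
autocorrelation of structured cohorts and is the null for "is this structure
real" questions.

**Saturation** subsamples cells (default sizes 20/30/40, 20 repetitions) and
reports the Jaccard index and coverage ratio of the subsample NAD set
against the full-cohort set.

## Divisive clustering

Cells are featurized by per-chromosome coverage of cohort NAD bins and
clustered with DIANA (divisive analysis): starting from one cluster,
repeatedly split the cluster with the largest diameter by seeding a splinter
group with the object of maximal average dissimilarity and moving objects
whose average dissimilarity favours the splinter (largest positive
difference first), until no positive difference remains; stop at k clusters.
Dissimilarity is Euclidean on raw coverage fractions (no standardization by
default, flag available). Ties break toward the lowest object index so the
split sequence is deterministic. The implementation reproduces the reference
R implementation's partitions and split heights exactly on a frozen fixture
(see tests).

## Bootstrap enrichment

For two bin sets and a per-bin signal (e.g. a histone-mark RPKM track), the
observed statistic is the difference of set means over non-missing bins. The
null resamples both groups, sizes preserved, from the pooled bins with
replacement (1000 iterations by default; a label-permutation alternative is
available since the procedure is sometimes described either way). The
one-sided empirical p-value uses the +1 correction, p = (#{null ≥ obs} + 1)
/ (iters + 1), so finite resampling can never report p = 0; the smallest
attainable p at 1000 iterations is 1/1001. Under a null signal the type-I
error at α = 0.05 is calibrated (checked over 200 repetitions).

## Numerical and degenerate-input choices

- Missing signal (bedGraph gaps) is NaN, never zero; enrichment statistics
  skip missing bins.
- A ≥ 1 bp overlap marks a bin contacted or LAD-typed; calls produced at the
  same window size make partial overlaps a merging artefact, so 1 bp is the
  lossless rule.
- Location tests default to the unequal-variance (Welch) two-sided t-test;
  identical zero-variance samples report p = 1. Multiple signal tracks are
  corrected with Benjamini–Hochberg.
- Gene CF aggregates as the maximum over overlapped bins (a gene touching a
  strong NAD is NAD-associated); mean available behind a flag.
- Quintile boundaries are computed on bin counts, not bp, so partial
  terminal bins do not skew the 5'-quintile analysis.
- RPKM follows 10⁹·C/(N·L) with validation of positive N and L.

## Problem sizes used in the test and acceptance runs

Synthetic cohorts use the default ~2,850-bin genome with 53 cells (50 for
hybrid cohorts, 40 for clustering recovery), chosen as cohort sizes
representative of single-nucleolus studies while keeping each simulated
cohort under a second of compute. The false-positive calibration aggregates
eight replicate cohorts; the binomial oracle check covers all n ≤ 100 on a
five-point p grid; bootstrap calibration uses 200 repetitions of
1000-iteration bootstraps on 100-bin signals.

## Known limitations

- The false-positive model assumes exchangeable cells and a single global
  noise probability p; real per-cell debris rates vary.
- DIANA is O(n²)–O(n³) in cells; fine for cohorts of tens to hundreds of
  nucleoli, not for thousands.
- The generator does not model rDNA repeat sequences themselves (absent from
  reference assemblies), X-inactivation, or read-level artefacts.
- Bin counts, not SNV density, drive the allelic simulation; allele-specific
  mappability is out of scope.
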