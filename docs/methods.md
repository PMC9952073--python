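# Methods

`popscan` implements the statistical layer of a population-genomic
diversity-and-selection analysis for biallelic SNP genotypes: per-population
diversity, runs-of-homozygosity (ROH) inbreeding, linkage-disequilibrium
(LD) summaries, a two-statistic windowed selective-sweep scan, and
fixed-effect genotype–trait association for an F2 intercross. This note
records the models, the defaults, the numerical choices, and what the
bundled simulator does and does not emulate.

## Genotype representation and site filtering

Genotypes are stored as alt-allele dosages (0/1/2, −1 for missing) in a
samples × sites matrix, sorted by (chromosome, position), 1-based positions.
Phase is discarded: no statistic in the toolkit requires it. VCF is the
exchange format (read with cyvcf2; written as GT-only v4.2 text);
multiallelic records and indels are skipped on input with a logged count.
BED gene intervals (0-based half-open) are converted to 1-based inclusive
coordinates internally; analysis windows are 0-based half-open.

Site filters retain sites with minor-allele frequency ≥ `maf_min` (default
0.05) and call rate ≥ `call_rate_min` (default 0.9), MAF computed on
non-missing allele copies. Both thresholds are plain parameters because
published pipelines state them inconsistently often; the defaults here are
the stricter pairing. Filtering is idempotent and order-independent.

The functional classifier assigns each SNP one category with precedence
exon > intron > upstream/downstream > intergenic, using strand-aware flanks
of `flank_bp` (default 5,000 bp — a conventional annotation-tool default;
published category fractions depend on the full transcript-aware annotation
stack and are not a validation target for this simplified interval
classifier). A gene supplied without exon sub-intervals is treated as a
single exon-spanning feature.

## Diversity statistics

* Observed heterozygosity Ho: per individual, 1 − (homozygous / non-missing
  loci); population Ho is the unweighted mean over individuals.
* Expected heterozygosity He: per site, the small-sample-unbiased
  2p̂q̂·n/(n−1) with n non-missing allele copies; population He is the mean
  over sites (monomorphic sites contribute 0, sites with n < 2 are skipped).
  Per-individual aggregation is a conceivable alternative reading of the
  usual verbal definition; the per-site mean was chosen for estimator
  unbiasedness.
* Per-site nucleotide diversity π = 2j(n−j)/(n(n−1)) for j alt copies among
  n — the mean pairwise difference among allele copies, verified in tests
  against exhaustive pair enumeration.
* Windowed π divides the summed per-site π by the window's physical length
  (per-bp convention of vcftools' `--window-pi`), not by SNP count, so
  windows with unequal SNP counts are comparable and diversity ratios are
  well defined. Missing genotypes reduce n at a site; nothing is imputed.

## Runs of homozygosity and F_ROH

The detector reproduces the two-stage PLINK `--homozyg` scan with the
parameter set used for chicken-scale data: 50-SNP sliding windows, at most
1 heterozygote and 5 missing calls per window, minimum segment length
100 kb, minimum density one SNP per 50 kb, maximum inter-SNP gap 1,000 kb.
Stage one marks each window homozygous or not; stage two gives every SNP a
hit rate (homozygous windows containing it / windows containing it) and
marks SNPs with hit rate ≥ 0.05 eligible; maximal runs of consecutive
eligible SNPs — split at oversized gaps — become segments if they pass the
length, SNP-count (default 100) and density constraints. The hit-rate
threshold and minimum SNP count are the scanning tool's documented defaults;
both are exposed in `ROHParams`. Segment boundaries are first/last SNP
positions (the `.hom` dialect), so a planted tract is recovered up to the
flanking inter-SNP spacing. Chromosomes with fewer SNPs than one window
produce no calls.

F_ROH = Σ L_ROH / L_AUTO with L_AUTO defaulting to 960,280 kb, the
SNP-spanned autosomal map length of the chicken dataset this layer was
built around; it is an ordinary parameter and should be set to the map
length of the data at hand. The implementation is checked against an
independently coded naive re-scan on hundreds of random instances.

## Linkage disequilibrium

r² is the squared Pearson correlation of genotype dosages (composite LD on
unphased data) with pairwise deletion of missing calls; a pair is undefined
(NaN, excluded from curves) if fewer than two complete observations remain
or either site is then monomorphic. E[r²] ≈ 1/n for unlinked loci — the
small-sample bias — is used as a calibration property in tests. Decay
curves bin all intra-chromosome pairs by distance (defaults: 300 kb maximum
distance, 1-kb bins, typical LD-decay-tool settings; the defaults are
qualitative reporting choices, not fitted quantities). Pruning follows the
greedy `--indep-pairwise 50 5 0.2` procedure: within each 50-SNP window any
retained pair with r² above the ceiling loses its later member
(deterministic tie-break chosen for reproducibility), the window then
slides by 5 SNPs; the exported postcondition is that no retained pair that
can share a window exceeds the ceiling.

## Sweep scan

Windows are 40 kb sliding in 10-kb steps, truncated at chromosome ends, so
interior positions are covered by exactly four windows. Per window:

* **FST** — two-population Weir–Cockerham (1984) variance components from
  genotype counts (the estimator includes the observed-heterozygosity term,
  so no HWE assumption within populations), combined across the window's
  sites as Σa / Σ(a+b+c) (ratio-of-sums, the "weighted" dialect); the
  per-site mean is also emitted for comparison. Sites where either
  population has < 2 genotyped samples, or monomorphic across the pooled
  sample, are excluded. The estimator can be slightly negative with no
  differentiation; a fixed difference gives exactly 1.
* **π ratios** — ROD = 1 − π_target/π_control and log2(π_control/π_target),
  oriented so larger values mean diversity loss in the target population.
  Both are computed because they are rank-equivalent monotone transforms of
  one another; ROD is the default reporting statistic. Windows with
  π_control = 0 are undefined (NaN) under both. A fully swept window
  (π_target = 0 < π_control) has ROD = 1 and log2 ratio +∞ — the transform's
  limit — keeping the two statistics defined on identical window sets and
  rank-equivalent exactly where the signal is strongest.
* **Z(FST)** — (x − mean)/SD with sample SD over finite windows; NaN
  propagates. Z is monotone in FST, so thresholding on either yields the
  same candidate set; both are emitted.

Candidate selection takes the top q = 0.05 tail of each statistic using the
empirical order-statistic threshold with all ties included (a tied boundary
never silently drops windows), NaN windows excluded from the quantile;
joint candidates are the intersection of the FST and diversity-reduction
sets. Consecutive or overlapping joint windows merge into maximal regions;
a gene is selected under a statistic if its interval intersects any of that
statistic's candidate windows by ≥ 1 bp, and the reported overlap set is
the intersection of the two per-statistic gene sets.

## Association models

For an F2 intercross with a biallelic test SNP:

* Model I: Y = μ + G + H + f + e, with genotype G (3 classes), hatch H
  (2 levels), family f (7 levels) as categorical fixed effects.
* Model II adds b(W − W̄), the slaughter-weight covariate centered at its
  sample mean, for carcass traits.

Fits are OLS with reference-cell coding; the genotype effect is a partial
F-test on the genotype dummy block (with no interactions this equals the
Type III test). LS-means are model predictions averaged with equal weight
over the H × f grid (covariate at its mean). LSD pairwise comparisons are
unadjusted t-tests on LS-mean differences — for a genotype pair the
contrast reduces to the genotype dummies, so the SE comes directly from the
coefficient covariance with residual df. Degenerate inputs (constant trait,
single genotype class, constant covariate, rank deficiency) raise or return
the p = 1 path rather than crash. Multiple testing across traits is
reported raw, with a Benjamini–Hochberg column alongside.

## Synthetic data

`simdata` generates the structures the stages assume, with full ground
truth:

* **Populations** — Balding–Nichols: ancestral frequency per site uniform
  on (0.05, 0.95), population frequency Beta(p(1−F)/F, (1−p)(1−F)/F),
  genotypes Binomial(2, p_k) under HWE, missingness independent at 2% by
  default. The default scene is two populations × 50 samples, one 5-Mb
  chromosome, 25,000 SNPs, F = 0.1. Genome-wide Weir–Cockerham FST on such
  data converges to F, which the tests exploit for parameter recovery.
* **Sweeps** — the target population's allele frequency inside the stated
  interval is set to 1 − 0.05(1 − s): near-fixation rather than an explicit
  hitchhiking model. This produces the depressed-π/elevated-FST signature
  the scan detects but none of the haplotype structure of a real sweep — a
  deliberate simplification; passing tests demonstrate the scan's windowing,
  ranking and intersection logic, not power against realistic genealogies.
* **ROH tracts** — one sample's genotypes in an interval are overwritten
  with the per-site major homozygote (missing calls stay missing); other
  samples are untouched.
* **Genes** — non-overlapping intervals placed uniformly, exponential
  lengths (mean 20 kb), random strands, optional exon sub-intervals.
* **F2 traits** — genotypes segregate 1:2:1; Y = μ + a(g−1) + d·1[g=1] +
  hatch + family + β_W(W − W̄) + N(0, σ²); defaults n = 734 individuals,
  σ = 50 trait units, W ~ N(1500, 150²), modest hatch/family offsets.

The simulator has no recombination map, no LD decay with distance (LD
fixtures instead use explicit block constructions), no demography or
migration, and no phasing. Everything is a pure function of (config, seed).

## Problem sizes and numerics

The test-suite and acceptance-script simulations use 5,000–25,000 sites,
20–100 samples, and 5–20 replicate seeds per property — sizes at which the
estimator-recovery tolerances (±0.02 on FST at F = 0.15; ±10% on the
covariate slope; 5% ± 2% type-I error over ≥ 400 null fits) hold with
comfortable margins under the generator's own sampling noise. Oracle
comparisons (FST components, ROH re-scan, pairwise-π enumeration) are exact
to ≤ 1e-12. Quantile thresholds use order statistics, not interpolation.
Degenerate windows (no usable sites, zero control diversity) are NaN and
excluded from ranking rather than coerced to zero.

## Known limitations

* The sweep generator's near-fixation model cannot probe haplotype-based
  statistics or partial-sweep power; reported detection power is specific
  to the planted-signal construction.
* The FST estimator is the two-population form; multi-population scans run
  pairwise.
* The functional classifier is interval arithmetic over gene/exon spans,
  not a transcript-aware effect predictor.
* LD pruning reproduces the greedy windowed procedure's postcondition, not
  any particular tool's undocumented visiting order.
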