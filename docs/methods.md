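# Methods

## Study design

The package evaluates a genotyping array against a phased panel treated as
ground truth.  Samples are divided into *k* batches (default 10) that are
balanced within every population and overall; each batch in turn becomes the
test set, its genotypes are restricted to the array's manifest positions
with phase removed, and the remaining batches form the phased imputation
reference.  Imputed dosages from all folds are merged and compared with the
truth genotypes, stratified by population.  No sample is ever present in
both the test and reference sets of a fold; this is asserted at run time.

### Stratified batching

Within each population, samples are shuffled (seeded) and dealt so that
per-population fold counts differ by at most one.  Each population's
remainder samples (n mod k) are assigned to the folds with the smallest
current totals, ties broken at random under the seed.  By induction this
keeps overall fold sizes within one of each other as well — for a
2,504-sample cohort over five populations it yields four folds of 251 and
six of 250, and for a 1,008-sample single-population cohort eight folds of
101 and two of 100.

### Pseudo-array extraction

Manifest and panel variants are matched on chromosome and position.  When a
manifest states alleles that disagree with the panel's ref/alt at a matched
position, the site is skipped and logged rather than strand-flipped — a
conservative, auditable choice since a disagreeing record cannot be
oriented with certainty.  Panel records flagged multiallelic (multiple ALT
alleles, or several records at one position) are never matched.  Skips are
counted by reason.

## Imputation model

Imputation uses a diploid Li–Stephens haplotype-copying HMM operating
directly on unphased genotypes, so no separate phasing stage is needed.
The hidden state at each typed site is an ordered pair of reference
haplotypes (K² states).  Between adjacent typed sites separated by *d* bp,
each haplotype of the pair independently switches with probability
1 − exp(−θ·d) and lands uniformly on one of the K reference haplotypes
(switching to itself included).  Emission at a typed site with observed
genotype g is the probability of reading g from the state's allele pair
when each allele is misread with probability ε.  A forward–backward
recursion over typed sites, rescaled per site (linear scale, scaling
factors retained for diagnostics), gives posterior state probabilities; the
posterior at every typed site sums to one within 1e−9.

At an untyped site the per-haplotype posterior marginals of the two
flanking typed sites are interpolated linearly by base-pair distance and
contracted against the error-smoothed reference alleles
f(a) = a(1−ε) + (1−a)ε, giving a dosage in [2ε, 2(1−ε)].  Sites outside the
typed range use the nearest typed site's marginals.  Typed sites pass
through as the observed integer genotype; a missing call at a typed site is
treated as untyped for that sample.  A sample with no typed genotypes at
all receives the allele-frequency dosage 2·AF per site with a warning.

Parameters and defaults:

- θ (`switch_rate`): per-bp switch intensity, default 1e−8 — a human-scale
  recombination magnitude.  It should be set to the LD scale of the data;
  evaluations on the synthetic panels pass θ = 1e−5 to match the
  generator's per-bp crossover rate.
- ε (`error`): per-allele mismatch probability, default 1e−3; must lie in
  (0, 0.5).
- `max_ref_haplotypes`: cap on K (default 32), enforced by seeded
  subsampling of the reference.  Complexity is O(T·K²) per sample, so the
  cap trades accuracy for time; with founder-mosaic panels the marginal
  gain above K ≈ 64 is small while cost grows quadratically.
- `numerical_floor`: guard against exact underflow of the per-site scaling
  factor (default 1e−300).

Exactness of the recursion is verified against complete K²-path enumeration
on instances small enough to enumerate (K ≤ 3, ≤ 5 sites), where agreement
is at machine precision.  Dosages are invariant to reference haplotype
ordering, and when the reference contains the target's true haplotype pair
and ε → 0, masked-site dosages converge to the true genotype (provided the
typed profile identifies the pair uniquely).

An adapter contract (`ExternalToolConfig`, `impute_with_fallback`) allows
an external phase+impute tool chain to replace the built-in model: inputs
and outputs are exchanged as VCF (unphased GT for pseudo-arrays, GT+DS for
dosages).  A missing binary raises a feature-unavailable error or falls
back to the built-in model, per configuration.

## Imputation metrics

Per site, accuracy is the squared Pearson correlation between imputed
dosages and truth genotypes across the evaluated population's samples.
MAF and minor-allele count (MAC) are computed from the truth genotypes of
the full evaluated population — all merged test folds — rather than from
any single fold's reference; this is the documented choice where a
frequency source must be fixed.

Sites are assigned to left-open/right-closed MAF bins (0–0.01],
(0.01–0.05], (0.05–0.5], plus the union bin (0.01–0.5].  Exclusions, each
recorded with its reason so that scored + excluded always equals the input
count: multiallelic records (everywhere); monomorphic sites (MAF 0, r²
undefined); MAC < 2 within the rare bin; typed sites (the metric evaluates
imputation; flag-controlled); zero-dosage-variance sites (Pearson
undefined — reported as degenerate rather than counted as failures, since
scoring them 0 would conflate degeneracy with error).

Coverage is the fraction of scored sites with r² ≥ 0.8.  Per-chromosome
bin means of r² and coverage are aggregated across chromosomes as mean and
sample SD (ddof = 1); a single-chromosome report carries SD 0 with an
explicit flag.

## Polygenic scores

Scores follow pruning and thresholding: PGSᵢ(P_T) = Σⱼ 1{Pⱼ < P_T} xᵢⱼ β̂ⱼ
(strict inequality) over the clumped SNP set, across the threshold grid
{5e−08, 1e−07, 1e−06, 1e−05, 1e−04, 1e−03, 0.01, 0.1, 0.2, 0.3, 0.5, 1}.

- *Harmonization*: summary-statistic alleles are aligned to the panel's
  ref/alt; a swapped match negates β; A/T and C/G sites that would require
  a swap are strand-ambiguous and dropped (counted), as are unmatched
  records.
- *Clumping*: greedy — the unclumped variant with the smallest p-value
  (ties by chromosome, then position) indexes a clump; unclumped variants
  within ±250 kb on the same chromosome whose genotype r² with the index
  reaches 0.1 are removed; the index is retained.  Deterministic and
  independent of input row order; verified against a re-scanning
  brute-force implementation.  Clumping is performed once on the truth
  genotypes of the evaluation cohort (per population) and the retained set
  reused for both score sources, isolating imputation error from
  clump-set instability; a flag re-clumps per source instead.
- *Scoring sources*: truth scores use integer allele counts; array scores
  use expected dosages by default, with a hard-call (rounded) option.
- *Concordance*: Pearson correlation of the two score vectors per
  threshold (constant vectors flagged undefined and omitted from the
  mean/SD over the grid, SD ddof = 1), and ADPR — per sample the absolute
  difference of percentile rank, with percentile 100·(rank − 0.5)/N and
  mid-ranks for ties.  The percentile convention is a documented choice;
  any convention consistent across both vectors gives ADPR 0 for identical
  score orderings.

## Synthetic data generator

The generator emulates the inputs the design needs — a phased,
LD-structured, multi-population diploid panel; array manifests; GWAS-style
summary statistics — with the simplest mechanisms that produce the relevant
structure:

- *Panel*: founder-mosaic copying.  Site frequencies are drawn log-uniform
  on [maf_floor, 0.5] (rare-heavy spectrum); founder haplotypes are
  Bernoulli draws at those frequencies; each cohort haplotype is a mosaic
  of founders with per-interval switch probability recomb_rate × gap and a
  per-site mutation flip.  Defaults: 16 founders, 1 Mb chromosome,
  recomb_rate 1e−5/bp, mutation_rate 1e−3 — chosen so that squared
  genotype correlation decays over tens of kilobases while every MAF bin
  keeps at least dozens of sites at cohort sizes of a few hundred.
  Population structure comes from per-population Dirichlet founder
  weights; the `differentiation` knob (default 0.3) sets their spread.
- *Manifests*: uniform or MAF-weighted subsets of panel sites; the
  weighted strategy emulates the common-variant bias of real tag-SNP
  selection.  Neither reconstructs any commercial design procedure.
- *Summary statistics*: a chosen number of causal variants draw effects
  from N(0, causal_beta_variance) and p-values log-uniform below 5e−8;
  the rest receive small zero-centred noise effects and uniform p-values
  (clipped below at 1e−7 so the causal count below genome-wide
  significance is exact by construction).  P-values are assigned, not
  estimated: the pipeline consumes summary statistics, it does not run a
  GWAS.

What the generator does **not** emulate: coalescent genealogies and
demographic history, genotyping error and missingness of real arrays,
sequencing error in the truth panel, sex chromosomes, and indel/structural
variation.  Passing tests therefore demonstrate correctness of the
pipeline's computations and the qualitative density/LD behaviour, not
performance forecasts for any real array–population pair.

All generator and model randomness flows from explicit integer seeds; the
evaluation model derives its per-fold seeds from one master seed via
`numpy.random.SeedSequence`.

## Reference run sizes

The canonical demonstration (`arraybench.demo`) uses 2 populations × 200
samples, 5,000 variants on one chromosome, manifests at densities
0.02/0.1/0.5, tenfold cross-validation, K capped at 32 — sizes chosen to
keep a full run to roughly a minute on a single core while leaving every
MAF bin populated and the density gradient well resolved.  With a single
simulated chromosome the cross-chromosome SD columns are flagged
single-chromosome.

## Known limitations

- The built-in imputer's K cap bounds accuracy; absolute r² levels on the
  synthetic panels (e.g. ≈0.74 in the union bin at 50% density, K = 32)
  are below what production imputation servers achieve on real data with
  full references and state-space compression.
- Interpolating posteriors from typed flanks is exact only in the limit of
  dense typing; a full per-site recursion would differ slightly at long
  untyped stretches.
- Clumping on cohort truth genotypes uses the evaluation cohort itself as
  the LD reference; external LD panels are out of scope.
- Percentile and SD conventions (mid-rank percentiles, ddof = 1) are
  explicit choices where the literature leaves them unstated.
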