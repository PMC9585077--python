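# arraybench

Benchmark SNP genotyping arrays by mask-and-impute cross-validation.

Choosing a genotyping array is a real design decision in human genetics:
arrays differ by an order of magnitude in tag-SNP count and in which
populations their content was optimized for, and both imputation quality and
downstream polygenic-score (PGS) accuracy depend on that choice.
`arraybench` implements the standard evaluation design for this question.
Starting from a phased whole-genome panel treated as ground truth, it

1. splits the cohort into *k* population-stratified, maximally balanced
   batches (tenfold by default);
2. in each turn reduces the test batch to the array's manifest positions and
   discards phase ("pseudo-array" data), keeping the remaining batches as
   the phased imputation reference;
3. imputes the masked sites with a built-in diploid Li–Stephens
   haplotype-copying HMM (an adapter contract lets external phase+impute
   tools be slotted in instead);
4. merges the folds and scores the array.

Array performance is quantified by four metrics:

- **imputation r²** — per site, the squared Pearson correlation between
  imputed dosage x̂ᵢⱼ ∈ [0,2] and the true genotype across samples,
  stratified into MAF bins (0–0.01], (0.01–0.05], (0.05–0.5] and the union
  bin (0.01–0.5]; multiallelic sites are excluded everywhere and sites with
  minor-allele count < 2 are excluded in the rare bin;
- **imputation coverage** — the fraction of scored sites with r² ≥ 0.8;
- **PGS correlation** — Pearson correlation between pruning-and-thresholding
  scores, PGSᵢ(P_T) = Σⱼ 1{Pⱼ < P_T} xᵢⱼ β̂ⱼ over the LD-clumped SNP set
  (250 kb window, r² 0.1), computed from imputed dosages versus from the
  truth genotypes, across a 12-value p-value grid (5e-08 … 1);
- **ADPR** — the absolute difference of percentile ranking: per sample,
  |percentile under the array-derived scores − percentile under the
  truth-derived scores|.

A synthetic-data module (founder-mosaic haplotype panels with tunable LD,
manifests of any density, GWAS-style summary statistics) makes the whole
pipeline runnable and testable without any external downloads.

## Worked example

```python
import arraybench as ab

panel = ab.simulate_panel(ab.SimConfig(
    n_samples=200, n_variants=5000, populations=("POP1", "POP2"), seed=2022))
manifests = {f"density_{d:g}": ab.derive_manifest(panel, d, seed=101 + i)
             for i, d in enumerate((0.02, 0.1, 0.5))}
stats = ab.simulate_summary_stats(panel, ab.EffectModel(n_causal=100, seed=77))

model = ab.ArrayEvaluation(
    panel, manifests, {"trait1": stats}, k=10,
    hmm_params=ab.HMMParams(switch_rate=1e-5, error=1e-3, max_ref_haplotypes=32),
    seed=1)
results = model.fit()
print(results.summary())
```

On one CPU this tenfold run finishes in about 70 s and prints (seed 1):

```
Array evaluation (mask-and-impute cross-validation)
  samples: 400  variants: 5000  folds: 10

  Imputation, MAF bin (0.01,0.5] (r2 cutoff 0.8):
  array                population   mean r2   coverage   sites
  density_0.02         POP1          0.2213     0.0060    3145
  density_0.02         POP2          0.2027     0.0034    3218
  density_0.1          POP1          0.6170     0.1239    2897
  density_0.1          POP2          0.5887     0.0992    2963
  density_0.5          POP1          0.7434     0.3842    1637
  density_0.5          POP2          0.7199     0.3313    1663

  PGS concordance to WGS (mean over p-value grid):
  array                population   trait        corr      ADPR
  density_0.02         POP1         trait1       0.4438   24.269
  density_0.1          POP1         trait1       0.7933   13.496
  density_0.5          POP1         trait1       0.9751    4.436
  density_0.02         POP2         trait1       0.4313   24.540
  density_0.1          POP2         trait1       0.7909   14.474
  density_0.5          POP2         trait1       0.9600    5.466
```

Reading it: a 2%-density array tags too few sites for the copying model to
track haplotypes between markers (mean r² ≈ 0.21, essentially no sites reach
the 0.8 coverage cutoff), while the 50%-density array recovers most common
variation (r² ≈ 0.73) and yields polygenic scores nearly interchangeable
with truth-genotype scores (correlation ≈ 0.97, mean percentile displacement
≈ 5 points).  Denser arrays are strictly better here because the synthetic
manifests are random subsets; on real arrays, content optimization for a
population can beat raw density.

The same objects accept real data: `ArrayEvaluation.from_files(...)` reads
phased panels from VCF, manifests and summary statistics from TSV.  A thin
CLI wraps the library (`arraybench simulate|evaluate|report --help`).

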