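# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `ipmsnet`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from an external run.

## 1. IP-MS processing and interactor calling

### Processing chain

1. **Log2 transform + median normalization.** Each sample's observed
   intensities are log2-transformed and shifted so the sample median is 0.
   Centering at 0 (rather than at any global constant) makes downstream
   log2FC values invariant to the normalization target; a sample with fewer
   than two observed values is rejected. Zero intensities are treated as
   non-detection (missing) because MS quantification reports conventionally
   write 0 for proteins without a signal.
2. **Evidence filters.** Removed: non-human and uncharacterized entries;
   contaminants via a configurable regex list over symbols and accessions
   (defaults: `KRT*`, `KRTAP*`, trypsin identifiers); unresolved isoforms,
   defined as ≥2 accessions mapped to the same gene whose intensity vectors
   (including the missingness pattern) are identical across all samples, in
   which case all members of the group are removed; proteins supported by
   fewer than 2 unique peptides. Each rule reports its hits independently, so
   the surviving set is the complement of the union and is order-independent.
3. **Imputation.** Per sample, missing cells are drawn from
   `Normal(μ_s − shift·σ_s, (width·σ_s)²)` with `shift = 1.8`, `width = 0.3`,
   where `μ_s, σ_s` are that sample's observed mean and SD (per-sample, not
   pooled — the convention of the standard desktop tool for this step). This
   is a left-censoring model: it presumes values are missing because they sit
   below the detection limit.
4. **Replicate log2FC.** `logFC_{g,i} = bait_i − control_i`, paired by
   replicate index; unequal bait/control replicate counts are rejected
   because the pairing would be undefined.

### Moderated one-sample test

Prior df `d₀` and prior variance `s₀²` are estimated by moment matching on
`e_g = ln s²_g − ψ(d/2) + ln(d/2)` over rows with positive sample variance:
`ψ′(d₀/2) = max(var(e) − ψ′(d/2), 0)` solved by bracketed root finding
(`d₀ = ∞` when the max is 0, in which case the statistic is a z-score against
`s₀² = exp(mean(e))`), and `s₀² = exp(mean(e) + ψ(d₀/2) − ln(d₀/2))`.
Zero-variance rows are retained — shrinkage defines their statistic — but are
excluded from hyperparameter estimation (their `ln s²` is −∞). P-values are
two-sided; the directional `log2FC > 0` gate is applied separately at calling
time, with the FDR cutoff inclusive (≤ 0.1) and the fold-change cutoff strict
(> 0). The implementation reproduces limma's `eBayes` hyperparameters and
t/p values to ~1e-12 on random fixtures, reduces exactly to the classical
one-sample t-test when `d₀` is forced to 0, and the test suite re-derives the
moment estimator independently as an oracle.

Dataset QC passes when the mean pairwise Pearson correlation of replicate
log2FC vectors exceeds 0.6 **and** the bait itself is called significant.
QC metrics include detected/significant counts, ribosomal counts (case-
insensitive RPL-/RPS- prefix), and, when a reference edge list is supplied,
the significant-vs-known overlap with a one-tailed hypergeometric p against
the detected background.

## 2. Networks

Combination rules: significant in ≥1 contributing dataset → interactor;
detected in ≥1 but significant in none → non-interactor; all index (bait)
proteins excluded from both lists. An index protein called significant in
another bait's IP keeps its bait–bait edge (so index–index links survive for
plotting and prioritization) but never enters the interactor/non-interactor
lists used as enrichment backgrounds. Edge identity is the unordered
gene-symbol pair; a bait enriching itself is a QC fact, not an edge. For the
cell-type partitions (EC only / SMC only / Intersect / Union) the
non-interactor background is the union of the contributing cell types'
non-interactors minus that partition's interactors — the minimal extension
consistent with the per-network rule; this is a design choice, recorded here
because no published convention fixes it.

## 3. Enrichment statistics

The hypergeometric upper tail `P(X ≥ x)` is accumulated in log space
(gammaln + logsumexp); the observed overlap is included in the tail. The test
suite proves exact agreement with full enumeration over all `C(N, n)` draws
for every valid configuration with `N ≤ 12`. Bonferroni denominators are the
number of sets actually tested in the family, computed at run time, never
hard-coded. Tissue enrichment is the same operation with tissue gene sets as
the collection. Wilcoxon rank-sum comparisons use exact enumeration when
`min(n_a, n_b) ≤ 8` with no ties and the tie/continuity-corrected normal
approximation otherwise; two samples with all values identical return p = 1
with a warning.

## 4. Genetics

* **SNP→gene annotation:** ±50 kb symmetric flank (strand ignored), MHC
  treated as the closed interval chr6:28,500,000–33,400,000; a SNP may serve
  several genes.
* **Gene-based test (SNP-wise mean):** `m·T = Σ z_j²` with
  `z_j² = χ²₁`-quantile of the SNP p-value; null `Σ λ_i·χ²₁`, λ =
  eigenvalues of the reference-panel dosage correlation matrix (negative
  eigenvalues floored at 0, values ≤ 1e-8 dropped). The tail probability
  uses Imhof's characteristic-function inversion evaluated by vectorized
  composite Simpson quadrature: the truncation point grows until the
  first-order integration-by-parts remainder is below 1e-11, the grid
  resolves the oscillation period `4π/q` with ≥24 nodes (≥20,000 overall),
  and a first-order oscillatory tail correction is added. Against
  high-accuracy adaptive quadrature the absolute error is ≤ ~1e-4 over a
  broad random sweep, and against `χ²_m` closed forms it agrees to ~1e-9.
  If the scheme reports an invalid value, the Satterthwaite scaled-χ²
  moment match (`scale = Σλ²/Σλ`, `df = (Σλ)²/Σλ²`) is used instead. A
  single-SNP gene returns the SNP p exactly. Gene p-values are clamped to
  [1e-300, 1 − 1e-16] before the probit Z.
* **Competitive gene-set test:** OLS of gene Z on membership + log gene
  length + log SNP count over the chosen background; one-tailed p for a
  positive membership coefficient from the t distribution; constant
  covariates are dropped with a warning; a degenerate fit (constant Z)
  returns β = 0, p = 0.5. The analytic p ignores gene–gene correlation of
  Z-scores (neighbouring genes share SNPs through the ±50 kb windows), so a
  permutation mode re-draws membership labels within the background to form
  an empirical null. Calibration holds when membership is unrelated to the
  signal's genomic layout; a member set forming one contiguous LD block is
  exactly the situation where the analytic test over-rejects — use the
  permutation mode there.
* **LD clumping:** locus members are all same-chromosome panel SNPs with
  squared Pearson dosage correlation (pairwise-complete, genotype not
  haplotype r²) strictly above 0.6 to the index variant; boundaries are the
  outermost member positions ± 50 kb, floored at 1 bp. Monomorphic partners
  carry no LD information and are skipped. Loci are never merged: each index
  variant keeps its own locus, and deduplication happens only in the
  unique-gene summary of the prioritized table.

## 5. Synthetic data: what it emulates, and what it does not

* **IP-MS:** log2 intensities `Normal(base_g, noise_sd/√2)` around baselines
  `base_g ~ Normal(25, 2)` (typical MS1 scale, exercising median
  normalization). `noise_sd` (default 0.5) is the SD of one replicate's
  log2FC, so each intensity cell carries `noise_sd/√2`. True interactors and
  the bait gain `effect_size` (default 2.0) log2 units in bait samples.
  Missingness is logistic in the underlying log2 intensity with slope
  `mnar_steepness` (default 3.0 per log2 unit — a sharp detection limit,
  matching the left-censoring premise of the downshifted imputation), with
  the midpoint calibrated by bisection to hit the target overall rate
  (default 0.1). Contaminant rows carry keratin-style symbols; low-evidence
  rows carry a single unique peptide. An optional `background_sd` (default 0)
  adds zero-mean per-protein bait-vs-control shifts; the demonstration study
  sets 0.7 because in real IPs the replicate log2FC correlation (the >0.6 QC
  regime) is driven by heterogeneous non-specific binding, not by the handful
  of true interactors. With `background_sd > 0` the "non-interactors have
  expected log2FC 0" property holds marginally, not per protein — background
  binders with genuinely shifted ratios are then correctly called
  significant, which is faithful to real data.
* **Genotypes:** haplotypes are latent AR(1) Gaussians (adjacent correlation
  `rho`) thresholded at the allele-frequency quantile; diploid dosage is the
  sum of two independent haplotypes. Genotype-scale r² is attenuated
  relative to the latent `rho` by the double thresholding (a latent 0.9
  yields adjacent dosage correlation ≈ 0.55 at uniform MAF 0.05–0.5) — a
  deliberate, cheap LD model, not a coalescent simulation.
* **GWAS:** per-SNP z ~ MVN(mean, R) with R the panel correlation
  (eigenvalues floored at 1e-8 before factorization); the mean is lifted by
  the effect size inside causal gene bodies.
* **Gene sets:** uniform random samples, except designated sets whose
  overlap with a designated gene list is forced exactly.

Passing tests on these generators show that the statistics are calibrated
and powerful **under the stated generating model**. They do not establish
performance on real IP-MS data, whose noise is heavier-tailed, whose
missingness mixes censoring with stochastic peptide sampling, and whose
interaction truth is unknown.

## 6. Study conditions and problem sizes

The calibration studies run at: FDR calibration — 200 pure-null datasets of
5,000 proteins with 2+2 replicates on complete matrices (the pure-null
configuration also fixes `missing_rate = 0`); spike recovery — 50 datasets
with 50 spiked proteins of 5,000 at effect 2.0, log2FC noise 0.5; imputation
— ≥10⁴ imputed cells; gene-test calibration — 2,000 null genes with 10 SNPs
in AR(1) ρ = 0.5 LD; competitive test — 400 null and 100 signal simulations
on an 80-gene, 400-SNP genome with membership re-drawn per simulation;
clumping — brute-force comparison on three panels across ρ ∈ {0.3, 0.8,
0.95}. The end-to-end demonstration study uses 400 genes on two chromosomes,
3 baits × 2 cell types, 300 proteins per IP, a 400-sample/1,600-SNP panel,
and GWAS signal (z-lift 2.0) in the 40-gene designated interactor pool.

With the default 10% MNAR missingness instead of complete matrices, spike
recovery degrades (recall ≈ 0.4, precision ≈ 0.55 at the same conditions):
downshifted imputation inflates the pooled variance prior and occasionally
manufactures positive log2FC for proteins observed in bait but censored in
control replicates. This is a known artifact of left-censored imputation at
R = 2, inherited by design from the emulated workflow, and is the main
reason the calling statistics are benchmarked on complete data.

## 7. Determinism and reproducibility

A single top-level seed derives per-component substreams
(`numpy.random.SeedSequence`); identical config + seed reproduces every
table byte-for-byte (asserted in the CLI tests). Every analysis constant —
the log2FC and FDR gates, the correlation gate, r² threshold, flank window,
imputation width/shift, MHC interval — lives in `PipelineConfig`; a
config-override test verifies there are no hidden copies. Each CLI stage
writes a manifest with the config hash, seed, package versions and row
counts so filter attrition is auditable.

## 8. Known limitations

* The gene-based and competitive tests are principled reimplementations of
  the SNP-wise mean model and the competitive regression; they are not
  bit-compatible clones of the external genetics toolchain (reduced
  covariate set; analytic mode ignores gene–gene Z correlation, offered via
  permutations instead).
* The hypergeometric conditional background assumes gene symbols are the
  join key throughout; accession-level ambiguity beyond the unresolved-
  isoform rule is not modelled.
* Genotype r² uses unphased dosages; haplotype-level r² would differ in
  strongly structured regions.
* The social Manhattan table places each gene at its locus midpoint and tags
  it with its locus index SNP; genes spanning multiple loci keep one point
  per locus before deduplication.
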