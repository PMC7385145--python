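# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data generator does and does not emulate.

## Phenotypic models

The unit of analysis is the per-environment adjusted entry mean of an
inbred genotype (the output of a preceding per-trial adjustment, which is
out of scope here). Two fits of the same two-way model are used:

1. **Variance components** — `y_ij = μ + G_i + E_j + e_ij` with genotype
   and environment crossed random effects. The REML criterion is profiled
   over the residual variance and optimized over the two variance ratios
   (γ_G, γ_E) with L-BFGS-B bounded at zero; negative-component solutions
   are therefore impossible, and estimates on the boundary are clamped to
   exactly 0 and flagged through `VarianceComponents.converged`. The
   likelihood is evaluated through the Woodbury identity, so the only dense
   factorization is of an (nG+nE)×(nG+nE) capacitance matrix — a 372-line ×
   8-environment panel fits in milliseconds. Optimizer tolerance is 1e-12
   on the criterion (≈1e-8 relative on the log-likelihood); two starts
   (unit ratios and method-of-moments) guard against local optima. On
   balanced complete data the REML solution coincides with the ANOVA
   method-of-moments estimators, which is used as a test oracle.

2. **BLUEs** — the same model with genotype fixed (full incidence, no
   separate intercept, so each coefficient is the predicted genotype mean
   on the trait scale — this removes the intercept-reparameterization
   ambiguity and makes the balanced-case identity with plain genotype
   means exact). The environment variance ratio is re-estimated by a 1-D
   bounded REML search on log γ in [−18, 16]; the lower boundary is treated
   as γ = 0.

Heritability is the entry-mean ratio `H² = σ²_G / (σ²_G + σ²_e/nE)`. It is
exact arithmetic on the fitted components; no shrinkage or rounding beyond
the reported decimals. Averaged correlations use the Fisher-z transform,
which requires every input strictly inside (−1, 1).

## Marker QC

Rates are computed on observed calls before imputation. Heterozygous calls
(dosage 1) count toward the heterozygosity rate and are excluded from the
allele-frequency computation, mirroring the "missing or heterozygous"
grouping conventional for inbred panels. Removal rules: MAF < 0.05
(boundary retained), missing rate > 5%, het rate > 5% (strict). A marker
failing several rules is counted once, in the order MAF → missing → het.
Imputation assigns the marker mean dosage over observed homozygous calls;
fractional dosages are permitted downstream because every consumer (GRM,
GWAS, prediction kernels) centers dosages anyway. The filter is idempotent.

## LD and structure

LD is computed as the squared Pearson correlation of dosage vectors, which
for fully inbred 0/2 data equals the haplotype-frequency formula exactly
(tested against direct frequency counting); with residual heterozygotes it
is the usual composite approximation. The decay profile takes all
within-chromosome pairs up to a distance cap, ordered by cM with ties
broken by marker id, and summarizes per distance bin (default 1 cM) by
median and mean. PCA operates on the column-centred dosage matrix via SVD;
variance proportions are singular values squared over total variance.
Whether PCA should use all quality markers or only mapped ones is not
fixed by convention; the default here is all quality markers (mapped-only
is a caller-side subset).

## GWAS

The association model adds one tested marker at a time to fixed covariates
(intercept, optionally the first 3 PCs) and a polygenic background with the
VanRaden method-1 GRM. The polygenic variance ratio δ = σ²_e/σ²_a is
estimated **once** under the no-marker model (P3D/EMMAX strategy) by a 1-D
profiled REML search on log δ in [−10, 10] in the eigenbasis of G; every
marker is then tested by GLS in that rotated basis with a Wald t-test on
n − c − 1 degrees of freedom. The naive variant is literally OLS, which
makes the OLS t-test an exact oracle. An exact per-marker REML scan exists
behind `GwasModelSpec(per_marker_reml=True)`; it is slower and differs
slightly from P3D at strongly associated markers (the marker then absorbs
genetic variance), which is expected and documented rather than hidden.
Markers whose residual (after projecting out covariates) has essentially
zero norm are reported `non_estimable` instead of producing spurious
P-values. Kinship matrices with negative eigenvalues from roundoff are
clipped to PSD with a warning.

FDR control is Benjamini–Hochberg step-up (the generic FDR convention) at
the liberal q = 0.20 appropriate for declaring candidate regions rather
than confirmed loci.

**p_G.** All declared MTA enter one multiple regression of the BLUEs;
`R²_adj = R² − (z′/(N−z′−1))(1−R²)` and `p_G = (R²_adj/H²)×100`. Per-marker
contributions are apportioned by sequential (type-I) sums of squares under
the entry order. The literature phrase "in the order of their descending
P-values" is ambiguous (read literally it enters the least significant
marker first); the default here enters most-significant-first (ascending
P, ties by |β| descending then marker id), and the order is an explicit
parameter (`ascending_p`, `descending_p`, `as_given`) so either reading
can be reproduced. Note that p_G can exceed 100 slightly when R²_adj/H²
does — both are estimates.

## Genomic prediction

* **GBLUP** re-estimates (σ²_a, σ²_e) by spectral REML on each training
  fold (not globally — folds stay independent), then predicts test lines by
  the conditional mean on the partitioned GRM. Algebraically identical to
  ridge regression on centred dosages at λ = δ·(2Σp_k(1−p_k)); the test
  suite verifies this to 1e-6.
* **BayesB** uses a spike-slab prior with marker-specific
  scaled-inverse-χ² variances. Hyper-parameter defaults follow the
  built-in rules of standard Bayesian whole-genome regression software:
  df_β = 5, π₀ = 0.5 with a weak Beta prior (prior count 10), the slab
  scale solved so the prior genetic variance matches R² = 0.5 of the
  phenotypic variance, and residual scale matching the remaining half.
  Chain defaults are 12,000 iterations / 2,000 burn-in / thin 5; tests and
  the acceptance script run 1,500–6,000-iteration chains, which this
  sampler's mixing comfortably supports at desk scale (n ≈ 200–300,
  p ≈ 400–1,000). The Gibbs kernel is numba-compiled and seeded inside the
  kernel, so a run is a pure function of (data, config, seed). The
  optional Gamma update of the slab scale is off by default (fixed
  heuristic scale); with π fixed at 1 and fixed variances the sampler
  degenerates to Bayesian ridge, which the tests exploit as an oracle.
* **RKHS** builds `K_ij = exp(−h d²_ij/p)` from squared Euclidean dosage
  distances and solves the same kernel mixed model as GBLUP. The bandwidth
  is chosen from {0.1, 0.5, 2.5} by an **inner** five-fold CV on the
  training lines only — nesting avoids information leakage from the test
  fold, at the price of a slightly noisier h choice; ties go to the
  smaller bandwidth. The chosen h is reported per fold.

The CV harness draws a fresh seeded partition per cycle (every line in
exactly one test fold), computes per-fold accuracy `cor(y, ŷ)/√H²` — the
standardization is by the square root of H², never H² itself — and pools
all cycle×fold values for the reported mean and SD (per-cycle means are
also exported). Folds with fewer than 3 test lines or constant vectors are
skipped with a warning rather than contributing undefined correlations.

## Candidate-gene diversity

Haplotype counting compares sequences only at sites where both are
unambiguous A/C/G/T; a sequence indistinguishable from an existing
haplotype under this rule collapses into it (greedy, first match in input
order — the relation is not transitive, so an order-free definition does
not exist; input order is the documented tie-break). Nucleotide diversity
is the unbiased mean pairwise difference per comparable site, without
multiple-hit correction (intra-species, low-divergence data). SS/NS
classification compares whole codons to the reference, so multi-hit codons
are classified once by their amino-acid change; each distinct
(codon position, variant codon) counts once across the alignment. Codons
interrupted by gaps or ambiguity are skipped and tallied; indels are
counted as events, never classified; a trailing partial codon is excluded
with a warning.

## Synthetic-data generator

The generator emulates the statistical regime of an elite European inbred
wheat panel: 372 fully homozygous lines (dosages {0, 2}; heterozygous and
missing calls only via explicit noise rates, to exercise QC), ~26,700 SNPs
on 21 chromosomes, weak continuous structure, block-wise LD, and
multi-environment traits with entry-mean H² around 0.9.

* **Structure**: Balding–Nichols — ancestral frequency p ~ U(maf_min,
  1−maf_min), subpopulation frequency Beta(p(1−F)/F, (1−p)(1−F)/F). The
  default F = 0.05 with two balanced subpopulations puts the first two PCs
  near 10% of marker variance, the weak-structure regime of recently
  registered variety panels.
* **LD**: founder-haplotype mosaic — within each block (Poisson sizes,
  mean 20 markers) every subpopulation carries 8 founder haplotypes; each
  line copies one founder per block with a 2% per-marker redraw. This
  yields high within-block r² decaying across block boundaries; it is not
  coalescent-exact and makes no attempt at realistic allele-frequency
  spectra, recombination maps, or selection history.
* **Traits**: additive QTL effects (gaussian / equal / geometric families)
  on centred dosages, optional pairwise epistasis as products of centred
  dosages, environment main effects, and i.i.d. residuals whose variance
  is solved so `Var(g)/(Var(g)+σ²_e/nE)` hits the target — the same
  entry-mean basis as the H² estimator, so recovery tests compare like
  with like. There is no genotype-by-environment interaction, no
  growth-habit covariate, and no spatial field structure; passing recovery
  tests therefore demonstrates correctness of the estimators under the
  stated model, not robustness to those real-data complications.
* **CDS alignments**: gapless coding sequences, one substitution per
  mutated codon, no stop codons, each mutation carried by a random
  non-empty subset of non-reference sequences, with a ledger of
  synonymous/nonsynonymous status for cross-module consistency checks.

All generator draws are pure functions of their config seed; pipeline
stages derive named substreams from the single global seed
(SHA-256-derived 31-bit children), so stages re-run in isolation reproduce
the full run.

## Problem sizes

Tests and the acceptance script run at desk scale — panels of 200–400
lines × 400–2,000 markers, 10–20 replicate seeds for calibration and
recovery experiments, 5–20 CV cycles, and BayesB chains of 1,500–6,000
iterations — chosen as the smallest sizes at which the statistical
contrasts of interest (null calibration, component recovery within ±15%,
model ordering on sparse vs epistatic architectures) are stable across
seeds. The library itself has no such limits; the full-scale defaults
(372 × 26,694, 100 cycles, 12,000-iteration chains) are the configured
defaults of `SimConfig`, `cross_validate` and `BayesBConfig`.

## Known limitations

* The two-way REML assumes at most one record per genotype×environment
  cell (adjusted entry means); replicated raw plot data must be adjusted
  upstream.
* P3D P-values are mildly conservative at very large-effect markers
  relative to exact per-marker REML (available behind a flag).
* The composite-LD r² and the GRM treat fractional imputed dosages as
  exact; with substantial missingness a dedicated imputation model would
  be preferable.
* BayesB's reported inclusion probabilities are per-marker; in tight LD
  blocks the posterior mass spreads across proxies, so architecture
  recovery should be judged at block resolution.
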