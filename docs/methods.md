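# Methods

## Model

An ML-CDN is a bipartite graph: cell lines on one side, drugs on the
other, edges labelled with observed normalized IC50 values (the set Ω).
Each side additionally carries a complete weighted similarity network.
Prediction is a Nadaraya–Watson-style weighted mean over Ω: the response
of (C, D) is the average of every observed response R(Cᵢ, Dⱼ), weighted by
the product of a cell-side kernel w(C, Cᵢ) = exp(−(1 − ρ(C, Cᵢ))²/2σ²) and
the analogous drug-side kernel with bandwidth τ. For a *tested* pair the
target's own entry is excluded from the sums (leave-target-out); same-cell
pairs (C, Dⱼ) and same-drug pairs (Cᵢ, D) are included and in practice
dominate. For a *new* sample nothing is excluded, since the sample is not
in Ω.

Because the prediction is a convex combination of observed responses, it
is always inside the observed range, and it is affine-equivariant: shifting
or rescaling all responses shifts and rescales every prediction the same
way. These two properties are asserted in the test suite.

The model's only free parameters are the bandwidths (σ, τ) ∈ [0, 1]².
They are fitted by exhaustive grid search with step 0.01 (101 × 101
points) on J(σ, τ) = Σ_Ω (R − R̂)², the sum of squared leave-target-out
errors. No gradient or adaptive optimization is used; the surface is
returned with the fit so it can be inspected.

### Numerical choices

* **σ = 0 (or τ = 0) limit.** The kernel is undefined at zero bandwidth;
  the limit convention w = 1 iff ρ = 1, else 0 is used, so the printed
  grid can start at 0 and the objective stays defined along its edges.
* **Vanished denominator.** If no weight reaches a target (e.g. at σ = τ =
  0 with no perfectly similar neighbours), the prediction falls back to
  the global mean of the observed responses and is flagged in
  `defined_mask`.
* **Leave-target-out without cancellation.** The sums excluding the target
  (i, j) are computed as [all pairs with k ≠ i] + [pairs with k = i,
  l ≠ j], never as [all pairs] − [target term]: the subtraction loses all
  precision exactly when the target's own weight dominates. The vectorized
  implementation agrees with an explicit double loop to 1e-10, which the
  test suite checks on 100 random instances.
* **Grid/objective consistency.** The grid search caches per-σ
  intermediates but performs bit-for-bit the same floating-point sequence
  as a standalone objective evaluation, so the surface matches per-point
  recomputation exactly.
* **Tie-break.** Argmin ties resolve to the smallest σ, then the smallest
  τ (first minimum in row-major order); a constant response matrix, where
  every J = 0, therefore returns (0, 0).
* **Similarities marginally above 1** (from rounding) are clipped; values
  above 1 + 1e-9 are rejected.

## Similarity layers

Cell lines: Tanimoto coefficient (|a∧b|/|a∨b|) on binary copy-number and
mutation status profiles; Pearson correlation on pathway-activity
profiles. Drugs: Tanimoto on structural fingerprints, Jaccard on target
profiles (identical to Tanimoto on binary data — kept as a named alias for
layer bookkeeping), and pairwise-complete Pearson on pan-cancer
sensitivity profiles (each drug pair correlated over its jointly observed
cell lines, requiring at least `min_overlap = 3` of them). Two entities
whose binary feature union is empty get similarity 0 with a warning: two
drugs with no recorded targets share no evidence of similarity. All
networks are complete graphs; no sparsification is applied.

## Fusion (SNF)

Multi-layer integration re-implements similarity network fusion:

1. Each similarity network becomes a distance matrix d = 1 − ρ (clipped at
   0). This monotone choice preserves similarity ranking and is recorded
   in the output metadata.
2. A locally-scaled Gaussian kernel W(i,j) = exp(−d²(i,j)/(μ·ε(i,j))) with
   ε(i,j) = (mean d(i, kNN(i)) + mean d(j, kNN(j)) + d(i,j))/3, floored at
   1e-12 so identical entities stay defined.
3. Cross-diffusion: each layer keeps a full kernel P (row-normalized so
   off-diagonal rows sum to 1/2, diagonal 1/2) and a sparse row-normalized
   K-nearest-neighbour kernel S; for t iterations P(v) ← S(v) · mean of
   the other layers' P · S(v)ᵀ, symmetrized and renormalized each step.
   The fused network is the symmetrized average of the final P matrices.

Defaults K = 20, μ = 0.5, t = 20 (K clamped to n − 1 with a warning on
small networks). kNN sets exclude self and break distance ties by entity
order, so the whole procedure is deterministic. There is no convergence
test; the iteration count is fixed. A single input layer is self-diffused
(the "other layers" mean falls back to the layer's own kernel), which
makes fusion of m identical inputs exactly equal to single-layer fusion —
a property the tests assert.

Fused similarities live on the diffusion scale (rows sum to ≈1, diagonal
≈1/2), not on the correlation scale; the decay-weight kernel only requires
ρ ≤ 1, and the grid search adapts the bandwidth to whatever scale the
supplied network uses.

## Preprocessing

* **IC50 normalization**: one global z-score per dataset — subtract the
  mean and divide by the sample standard deviation (ddof = 1) of *all*
  observed entries, not per drug, so all drugs share one baseline and
  range. Idempotent to 1e-9; the removed (mean, sd) is kept as metadata.
* **Copy-number binarization**: a gene is altered (1) iff its total copy
  number is ≥ 8 (amplification) or exactly 0 (deletion); anything strictly
  between is wild type. The package accepts per-gene total copy numbers;
  segment-level containment logic is upstream of this artifact.
* **Invariant-feature removal**: binary features that are 0 in every
  entity carry no pairwise information and are dropped.
* **Pathway activity**: per-gene z-scores across samples (ddof = 1),
  averaged over the pathway's member genes present in the matrix;
  pathways with fewer than `min_genes = 3` matched genes are dropped.
  A zero-variance gene contributes z = 0. This mean-z score is the
  simplest defensible gene-set summary and is invariant to per-gene affine
  rescaling of the input; alternative scorers can be substituted upstream
  since the similarity step only sees the resulting profile matrix.
* **Cohort homogenization**: restrict all cohorts to their common genes
  and standardize each gene within each cohort (location-scale
  adjustment). The downstream similarity is a correlation of
  pathway-activity profiles, which is invariant to exactly the location
  and scale this removes; full empirical-Bayes batch correction is out of
  scope.
* **Fingerprints**: 1024-bit hashed extended-connectivity (Morgan,
  radius 2) fingerprints via the optional rdkit backend; unparseable
  SMILES are excluded with a warning.

## Evaluation

Cross-validation splits the *observed pairs* (not cell lines or drugs)
into three near-equal folds with a seeded shuffle, remainders to the
earliest folds. Two folds fit (σ, τ); the held-out pairs are predicted
with the training Ω only and scored by Pearson r and RMSE, per fold and
pooled over all held-out predictions. The model-comparison harness runs
every CSN × DSN combination under either this protocol or a full-data
refit (`protocol="full_fit"`), since either reading of a 16-model
comparison is defensible; threefold is the default.

The association check regresses a predicted per-sample response on the
expression of one pathway's genes in a single OLS fit with intercept;
per-gene p-values come from coefficient t-tests and are
Bonferroni-adjusted within that regression (factor = number of gene
predictors), flagged at α = 0.05. Rank-deficient designs are rejected
with the collinear genes listed. Responder/receptor-status group
comparisons are thin wrappers over the standard two-sample t-test and
one-way ANOVA.

## Synthetic data

The generator plants the structure the model assumes. Cells and drugs are
assigned to blocks round-robin and shuffled; a block-mean response matrix
μ[a, b] ~ N(0, 1) defines ground truth; responses add N(0, noise_sd)
noise; a fraction of entries is masked uniformly at random. Each layer is
a noisy view of the same blocks: continuous pathway-like profiles are
block centroids plus N(0, 0.3) feature noise; binary layers are
block-specific Bernoulli(0.5) patterns with 5% per-entity bit flips; the
drug sensitivity layer is the (pre-masking) response transposed plus
independent noise, mirroring how pan-cancer IC50 profiles relate to the
response being predicted while avoiding exact leakage. Defaults: 50 cell
lines in 5 blocks, 40 drugs in 4 blocks, noise sd 0.1, 20% missing.

Ground truth is the noiseless block-mean matrix, so parameter-recovery
tests score model error separately from irreducible noise. What passing
these tests shows: the estimator, fitting loop, fusion and evaluation
machinery recover planted low-rank block structure under Gaussian noise
and random missingness. What they do not show: performance on real
pharmacogenomic marginals — realistic fingerprint bit densities, heavy-
tailed IC50 distributions, drug- or lineage-specific missingness, or
batch structure across cohorts.

## Problem sizes

The shipped tests and the acceptance script run the full 101 × 101 grid
on matrices up to 50 × 40 with three-fold cross-validation; these sizes
exercise every code path at comfortable desk scale, and the vectorized
grid evaluation (two small matrix products per grid point, with per-σ
caching) makes far larger screens practical.

## Known limitations

* Predicting a *new drug* absent from the DSN is out of scope (the
  symmetric use-case of new-sample prediction).
* Fused-network similarity values are not correlations; mixing fused and
  correlation layers in one model is allowed but their bandwidths are not
  comparable across layer types.
* The pairwise-complete Pearson used for sensitivity profiles is not
  guaranteed positive semidefinite as a matrix; nothing downstream
  requires PSD-ness.
* The mean-z pathway score ignores gene–gene correlation within a
  pathway; it is a profile summary, not an enrichment statistic.
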