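# Methods

## Models

### Penetrance-scale tree models

All inference operates on P(y = 1 | features), the penetrance scale,
without a link function. For a candidate interaction I = {A1..Ad}:

- **Epistasis (alternative) model** — a single CART with Gini splits over
  all d features; each leaf predicts the class-1 fraction of the training
  samples it holds.
- **No-epistasis (null) model** — `μ + CART1(I1) + CART2(I2)` over a
  bipartition (I1, I2) of I. The components are regression trees
  (variance-reduction splits) fit by backfitting: with μ = mean(y), the
  components are alternately refit to the residual of the other and
  re-centered to mean zero after every fit, until the training MSE
  improves by less than 1e-6 or 20 rounds have run. If a greedy refit
  ever increases training MSE the previous state is kept, so the
  recorded MSE path is monotone non-increasing. A component with nothing
  to explain collapses to a constant zero offset, so the null also covers
  responses that depend on only one group or on neither.
- For d = 2 the bipartition is simply ({A}, {B}). For 3 ≤ d ≤ 8, all
  2^(d−1) − 1 unordered bipartitions are fit on training data and the one
  with the lowest cross-entropy on the *test* data is used, because
  lower-order interactions within a group must remain available to the
  null. Selecting the partition on test data makes the null model
  slightly optimistic, which makes the final test conservative; this is
  deliberate and not corrected. Ties break toward the smaller first
  group, then lexicographically.

Summed null predictions are not constrained to [0, 1]; instead every
probability entering a likelihood is clipped to [ε, 1−ε] with ε = 1e-6.
This keeps log-likelihoods finite without distorting interior fits.

### Depth tuning

For each candidate separately, the depth grid 2..8 is scanned in order
and the smallest depth at which the single CART uses *every* feature of I
is selected; if none qualifies, the ceiling (8) is used and the candidate
is flagged (`all_features_used = False`), in which case the test almost
always screens to p = 1. The same depth and leaf-size floor are reused
for the null model's component trees so that null and alternative have
comparable complexity. Complexity is controlled by `max_depth` plus a
minimum leaf size `min_leaf = max(25, n/500)` rather than
cost-complexity pruning — the shallowest-sufficient-depth rule directly
implements the intent, and pruning would decouple null and alternative
complexity.

### PCS epistasis p-value

Prediction on the hold-out test set acts as a screen: if the epistasis
model's test cross-entropy is not strictly lower than the null's, the
p-value is 1 and no bootstrap is run. Otherwise, for b = 1..B the test
set is resampled with replacement at full size (no stratification); the
same resampled indices are used for the observed responses Y|b and for
null-perturbation responses Y0|b ~ Bernoulli(P0|b) drawn from the fitted
null probabilities (a paired comparison). With log T(Y) =
Σ_i [log Bern(y_i; p0_i) − log Bern(y_i; p1_i)], the p-value is the
fraction of resamples with log T(Y|b) > log T(Y0|b), using *strict*
inequality so ties count against rejection (conservative). Monte-Carlo
p-values live on the grid {0, 1/B, ..., 1}; a raw 0 is displayed as
"< 1/B". A diagnostic warns when the estimate at B/2 and B differ by
more than 0.01.

The large-B limit is available in closed form: conditional on the data,
the bootstrap difference D_b = Σ_resampled i [ℓ_i(y_i) − ℓ_i(Y0_i)] is a
sum of n iid draws of Δ = ℓ_I(y_I) − ℓ_I(Y0_I) with I uniform over test
observations and Y0_I ~ Bern(p0_I). Both moments of Δ are computable
directly from the test set, giving p ≈ Φ(μ_D/σ_D) by the CLT. This
approximation is validated only against the in-repo Monte-Carlo oracle
(agreement within 0.02 at B = 50 000 over datasets spanning weak to
strong evidence); σ_D = 0 degenerates to the exact indicator {μ_D > 0}.

Bonferroni correction (min(1, m·p)) is applied separately within the
gene-level and the SNP-level candidate sets, with m equal to the number
of candidates actually tested at that level (recorded in the run
manifest); a global-correction switch exists.

### Logistic comparator

For pairwise candidates, the classical test fits
`logit P = β0 + β1 a + β2 b (+ β3 ab)` on training data and reports the
χ²(1) LRT p-value for β3 plus both models' hold-out cross-entropies.
Separation or non-convergence yields a flagged record with p = NaN.

## Screening

Forests are grown with bootstrap-per-tree and Gini splits; the mtry
split-candidate features are drawn *without replacement with probability
proportional to a weight vector*. This weighted candidate sampling is
the defining ingredient of iRF and is implemented in a numba kernel
(no installed forest exposes it). Iteration 1 uses uniform weights; each
later iteration reuses the previous iteration's normalized Gini
importances. Defaults: 3 iterations, 500 trees, mtry = ⌈√p⌉,
min_leaf = 5 (screening forests favour depth; inference trees are tuned
shallow separately).

Candidate extraction: every leaf with predicted probability > 0.5
contributes the set of distinct features on its root-to-leaf path,
weighted by the leaf's class-1 training count (the balanced designs make
0.5 the natural class-1 cut). RIT defaults: depth 5, 2 children per
node, 500 trees, minimum prevalence 0.1 — the customary defaults of the
reference algorithm; prevalence is the fraction of all RIT leaves
producing exactly that feature set.

Stability: the entire iRF + RIT search is rerun on bootstrap resamples
of the training samples (default 50) with identical hyperparameters and
a derived per-replicate seed; an interaction's stability is the fraction
of replicates recovering exactly that feature set (superset matching is
available as an option, exact match is the default), and only stability
> 0.5 survives. The top-50 features by Gini importance additionally
contribute all inter-chromosome pairs as candidates
(`pairwise_expansion`); the union with RIT candidates enters inference,
with RIT metadata kept on duplicates. Interactions whose features share
a chromosome are removed (LD mimics epistasis); when genotypes are
available the removal log includes the max pairwise composite
(dosage-correlation) r², with 0.4 the reference threshold for "high" LD.

The two-step screen runs the gene level first (after PrediXcan-style
aggregation `score_g = Σ_j w_jg · dosage_j`), then restricts to SNPs
within ±1 Mb of the start/end of any gene in a surviving gene-level
interaction (1-based inclusive interval arithmetic) and rescreens.
Screening touches training samples only; this is asserted by an id audit
in the tests.

## Synthetic data

The generator emulates the target data regime: independent common
variants (dosage ~ Binomial(2, MAF), MAF ~ U(0.05, 0.5) or fixed),
block-structured chromosome layout with increasing positions, optional
copy-left-neighbour LD blocks, and sparse SNP→gene weight maps in which
one SNP carries a dominant fraction of the absolute weight mass
(normalized to Σ|w| = 1, random signs) — reproducing the stepped,
multi-modal gene-score distributions that imputed expression shows when
one variant dominates. Penetrance models: additive-on-logit,
marginal-only, multiplicative-on-logit, Boolean AND/XOR and higher-order
AND, with indicators 1[x > t] (default t = 0.5 on dosages, i.e. dominant
coding; feature median on gene scores) or a heterozygosity indicator
1[x == 1] for dominance-type effects. Balanced case-control assembly
simulates batches until both classes are filled, then splits stratified
train/test (default test fraction 2/15).

What the generator does *not* model: population structure, relatedness,
imputation uncertainty, realistic LD decay, sex-stratified effects.
Passing studies therefore demonstrate the statistical machinery under
idealized independence, not robustness to confounding in real cohorts.

## Study conditions (fixed once, used by tests and the results script)

- Type-I error: additive-on-logit truth with per-feature effect 0.4 at
  MAF 0.3, balanced n = 4000 split 50/50, B = 200.
- Power/ranking: Boolean-AND, p_hi = 0.8 / p_lo = 0.3, dominant coding at
  MAF 0.3, n = 4000, true pair among 19 disjoint decoy pairs, B = 500
  (resolution 1/500 comfortably below the Bonferroni cut 0.05/20).
- Screen recovery: n = 3000, 200 SNPs on 10 chromosomes, 20 genes of 3
  SNPs (dominant weight 0.7), AND in two cross-chromosome gene scores at
  median thresholds (0.8 vs 0.3); forest reduced to 15 trees and 2 iRF
  iterations with 100 RIT trees — the study's desk-scale configuration.
- XOR contrast: XOR of heterozygosity indicators at MAF 0.5
  (0.7 vs 0.3). At MAF 0.5 both the marginal dosage effects and the
  dosage-product term have exactly zero covariance with the signal, so
  the logistic LRT stays null-distributed while the CART models capture
  the dominance pattern — the cleanest construction of an epistasis form
  invisible to the multiplicative-logit comparator.
- Comparator calibration: β_int = 0 on the logit scale, n = 5000.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng`; every stage
  seed is a deterministic function of the master seed and the stage name
  (manifest + inputs replay to byte-identical outputs). Tree-level seeds
  for the numba kernel are drawn below 2^31.
- Tie-breaks are deterministic everywhere (lexicographic feature order,
  smallest group first).
- Inference CARTs are fit via scikit-learn's tree implementation and
  converted into the package's flat-array `TreeModel` (JSON
  serializable); the screening forest is the package's own kernel since
  per-split weighted candidate sampling is not expressible in
  scikit-learn.
- A threshold midpoint that rounds onto a sample value (adjacent floats)
  would create an empty child; the kernel detects this and declares the
  node a leaf.
- Degenerate inputs: constant responses give single-leaf trees;
  constant features give stump components; zero-variance variants are a
  hard error in LD computation; missing genotypes are rejected unless
  mean-imputed at read time (cohort data are assumed pre-imputed, so no
  in-pipeline imputation exists).
- Known limitations: the bipartition null is enumerated only to d = 8;
  the backfitting scheme is the classical alternating-residual form;
  bootstrap resampling of the test set is unstratified; the
  heterozygosity-XOR contrast scenario is a designed best case for the
  tree test, and results on real cohorts will be attenuated by LD and
  confounding that the generator does not model.
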