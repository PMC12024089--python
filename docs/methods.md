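# Methods

This note documents the models, algorithms and numerical choices behind
`shortscale`, and what the synthetic generator does and does not emulate.

## Synthetic response model

`generate_responses` draws from a second-order bifactor Gaussian model.  Item
*i* in subscale *s* has latent score

z_i = a_i·G + b_i·g_s + √(1 − a_i² − b_i²)·e_i,

with a general distress factor G, group factors g_s = √c·H + √(1−c)·u_s that
share a second-order factor H (so any two group factors correlate at *c*),
and independent unique errors.  The latent score is cut at four fixed
standard-normal thresholds into categories 1–5.  The implied latent
correlation is a_i·a_j + b_i·b_j for same-subscale pairs and
a_i·a_j + b_i·b_j·c across subscales (`expected_latent_correlation`).

Defaults (`scl90_like_spec`) were chosen once to emulate the statistical
shape of general-population SCL-90 data and are not tuned per analysis:

* **General loadings 0.62–0.80, group loadings 0.28–0.40**, spread
  deterministically across the 90 items (golden-ratio sequence) so items are
  not exchangeable.  SCL-90 full-scale alpha is typically ≥ 0.97, implying
  mean inter-item correlations near 0.45–0.5; these loadings, after
  discretization attenuation, reproduce that regime (observed mean r ≈ 0.41
  at n = 4808).
* **Group-factor correlation 0.30**: the subscales of symptom checklists are
  known to be strongly intercorrelated beyond the general factor.
* **Thresholds (0.5, 1.2, 1.8, 2.3)**: cutting to the right of zero makes
  category 1 modal and item means < 2, the positive skew typical of
  non-clinical samples (about 10–11 % of self-normed respondents cross the
  T ≥ 63 line, matching the skewed-outcome setting of the screening stage).

`generate_block_responses` instead plants an exchangeable block correlation
(`within_r` inside blocks, `between_r` across) and discretizes the same way;
it is the natural ground-truth fixture for clustering because the correct
partition is known by construction.

What the generator does **not** emulate: item-specific response styles,
acquiescence, missing data, floor effects beyond the threshold mechanism,
demographic heterogeneity, or any estimate of a real population's
parameters.  Tests passing on this model show the algorithms are correct and
well-behaved under the assumed structure, not that any particular item subset
generalizes to real survey data.

## Variable clustering

The divisive algorithm follows classical VARCLUS semantics:

1. All items start in one cluster.
2. The cluster whose correlation submatrix has the largest second eigenvalue
   above the threshold (default 1.0, the Kaiser-style cutoff; ties broken by
   lowest cluster index) is split: its first two principal components are
   quartimax-rotated (planar rotation maximizing Σl⁴, located by a 181-point
   grid plus bounded refinement — deterministic), and each member joins the
   component with which its squared correlation is larger.
3. A reassignment phase then moves any item to the cluster whose first
   principal component explains more of its variance, recomputing PCs each
   pass.  A pass is accepted only if it strictly increases the summed
   own-cluster explained variance Σγ, which makes the phase monotone and
   guarantees termination (cap 50 passes); a pass that would empty a cluster
   is rejected so each split increases the cluster count by exactly one.

All quantities are computed from the correlation matrix alone: the
correlation of item *j* with the first PC of a cluster with member index set
*A*, eigenvector v₁ and eigenvalue λ₁ is (C[j, A]·v₁)/√λ₁, so γ and ν need
no raw-data pass.  With a single cluster ν is taken as 0 (RS ratio = 1 − γ),
preserving minimal-RS selection semantics.  Representative ties break to the
smallest item id.  The sweep mode enumerates target cluster counts
k = 1..k_max directly rather than adjusting the eigenvalue threshold in
steps: the output semantics (a per-k solution path) are identical and the
enumeration is deterministic.

Pearson correlations are computed on the raw Likert scores (product-moment,
n−1 denominators), not polychoric correlations; the clustering operates on
the same correlation object the abbreviation regressions see.

## Abbreviation sweep

For each k the clustering, representative selection, Cronbach's alpha and the
GSI regression use only the training split (default 80 %); the test split is
touched only to evaluate each k's fitted regressor against the held-out
full-scale GSI.  The stopping rule is the first k with test Pearson
r ≥ `stop_r` (default 0.96, the best GSI correlation reported among existing
short forms of the instrument); if the sweep exhausts `k_max` the best
solution is returned flagged as not meeting the threshold.  Regressors:

* **OLS** via least squares on the (intercept-augmented) design; a
  rank-deficient design is an explicit error suggesting ridge.
* **Robust**: M-estimation with Huber's ρ, tuning constant 1.345 (95 %
  Gaussian efficiency), via IRLS.
* **Ridge**: penalty chosen by 5-fold CV over {10⁻³, …, 10²}.

`predict_subscales` fits one regression per subscale with the full-scale
subscale mean score as criterion, trained on train, evaluated on test.

## Reliability and factor structure

* **Alpha** uses the covariance form α = N·c̄/(v̄ + (N−1)·c̄) with n−1
  denominators (algebraically equal to (N/(N−1))(1 − Σvᵢ/var(total))).
* **Omega** is the one-factor form ω = (Σλ)²/((Σλ)² + Σθ) on the
  standardized solution.  Non-positive unique variances (Heywood) raise an
  error rather than being clamped.
* **EFA** is unrotated iterated principal-axis factoring (SMC start,
  communalities updated to convergence at 1e−6, cap 100 iterations) on the
  Pearson correlation matrix; the retained count follows Kaiser–Guttman
  (eigenvalues > 1) floored at 1 so a factor always exists.  Factor signs are
  fixed so each loading column sums positive.
* **CFA** minimizes the ML discrepancy F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p over
  λ and θ (Σ = λλ′ + diag θ) with analytic gradients under L-BFGS-B,
  objective tolerance 1e−10, 500-iteration cap, bounds θ ≥ 1e−6, and three
  deterministic starts (first-PC loadings, λ = 0.5, λ = 0.3), keeping the
  best objective.  χ² = (n−1)·F at the optimum; df = p(p+1)/2 − 2p.  The
  reported solution is standardized (λ² + θ = 1 exactly).  Fit indices:
  RMSEA = √(max(χ²−df, 0)/(df(n−1))); CFI and TLI against the independence
  baseline (χ²_b = −(n−1)ln|S|, df_b = p(p−1)/2); SRMR is the RMS of the
  lower-triangle (diagonal included) correlation residuals.  A
  just-identified three-item model (df = 0) reports SRMR from its residuals
  and the degenerate RMSEA = 0, CFI = TLI = 1.  Estimation is on Pearson
  correlations of the raw Likert scores (no polychoric/WLSMV estimator), so
  loadings are attenuated relative to the latent model — the attenuation is
  itself checked in tests against a Monte-Carlo discretization oracle.
* EFA and CFA are run on disjoint random halves of the sample
  (`split_half`), so exploration never certifies its own training data.

## Screening bench

The positive class is GSI T-score ≥ 63 (inclusive), with T-norms estimated
on the training sample and reused for test labeling to avoid leakage; no
external norm table is assumed.  Nested CV uses 10 stratified outer folds
and a 5-fold inner grid search selecting on F1 (appropriate for the ~10 %
positive rate; AUPRC selection available via the `scoring` argument).  Grids
are deliberately small and printed in `default_classifier_specs`: logistic
C ∈ {1, ∞} (L2 vs unpenalized); random forest 100/300 trees × depth 4/8;
AdaBoost learning rate 0.05/0.1; GBDT depth 2/3 × learning rate 0.05/0.1;
RBF-SVC C ∈ {0.1, 1, 10} with Platt-scaled probabilities.  No resampling or
class weights are applied — stratification only.  Label metrics use the
fixed 0.5 probability threshold; fold summaries report mean ± t₀.₉₇₅,₉·s/√10;
curves, AUROC (trapezoid ≡ tie-corrected Mann–Whitney), AUPRC
(step-interpolated average precision), the Brier score and 10 equal-width
calibration bins are computed from pooled out-of-fold probabilities.
`train_final` refits the chosen family on all rows with CV-tuned
hyperparameters and serializes it with a JSON metadata sidecar (item ids,
norms, threshold, version).

## Problem sizes and determinism

The acceptance script and end-to-end tests run the sweep at the study scale
(n = 4808, p = 90) — the whole sweep takes seconds because clustering works
on the 90×90 correlation matrix.  The pipeline-determinism check uses
n = 1500 with two classifier families, and the metric-oracle checks use
1000 random confusion fixtures; these sizes were chosen as the smallest that
exercise every code path with stable statistics.  Every stochastic component
(generation, splitting, CV folds, tree ensembles) is driven by named seeds;
two runs under one configuration produce identical item sets, traces and
fold assignments, which the test suite asserts.

## Known limitations

* Pearson (not polychoric) correlations understate latent associations for
  skewed ordinal items; all downstream quantities inherit this attenuation.
* The CFA offers no robust (mean/variance-adjusted) test statistics; with
  large n the χ² is expected to reject even mildly misspecified models, which
  is why the fit indices carry the interpretive weight.
* The quartimax split plus greedy reassignment is a local optimizer, as in
  classical VARCLUS; it is exact on well-separated planted blocks (verified)
  but has no global-optimality guarantee on adversarial structures.
* The generator's Gaussian-threshold model cannot represent differential
  item functioning or non-monotone item-factor relations.
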