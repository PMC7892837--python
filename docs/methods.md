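# Methods

`uromet` implements a biomarker-discovery pipeline for urinary metabolomics
in a two-group (case/control) design, together with a synthetic-cohort
generator that reproduces the statistical structure such data exhibit. The
motivating application is non-invasive detection of childhood neuroblastoma
from urine, where a vendor-quantified table of ~1000 metabolite relative
intensities per sample is refined down to a three-metabolite panel scored by
a linear predictive-value equation.

## Pipeline model

The analysis is a fixed cascade; each stage consumes the previous stage's
survivors.

1. **Normalization.** Urine concentration varies several-fold between voids,
   so every sample row is divided by its osmolality (rescaled to the cohort
   median so magnitudes stay comparable). Normalization is applied exactly
   once; a matrix already flagged normalized is rejected rather than
   silently re-scaled. Nondetects are imputed once at load with half the
   per-metabolite observed minimum — the conventional below-detection
   stand-in — with the imputed-cell count logged. The imputation fraction is
   configurable; the choice matters little to the rank-based screen but
   OPLS-DA requires complete data.

2. **Wilcoxon screen.** Relative intensities are heavy-tailed enough that
   parametric normalization fails, so each metabolite is tested with the
   two-sided Wilcoxon rank-sum test on raw normalized intensities (no log
   transform), cases vs controls, α = 0.05, **without** multiple-testing
   correction. That omission is deliberate: the screen is a refinement step
   whose survivors face three further, stricter filters; correcting here
   would trade false positives the later stages already remove for false
   negatives nothing can recover. (FDR/Bonferroni remain available behind a
   non-default flag.) The exact null is enumerated when the combined sample
   size is ≤ 12 and the pooled values are tie-free; otherwise the normal
   approximation with tie-corrected variance and continuity correction is
   used (the study's own 15 vs 39 design is firmly asymptotic). A degenerate
   metabolite with all values identical gets p = 1 by convention. Fold-change
   is the ratio of group medians — medians for consistency with the
   nonparametric test; configurable. Only pretreatment samples, one per
   subject, enter the screen, so repeated follow-up samples cannot
   pseudo-replicate.

3. **Exogenous exclusion.** Metabolites annotated exogenous (drugs and
   their conjugates) are removed after the test. They pass the screen
   precisely because treatment follows diagnosis; they are causally useless
   as tumour markers.

4. **Random-forest ranking.** The survivors are ranked by Breiman's
   out-of-bag permutation importance (mean decrease in OOB accuracy), which
   is comparable across features whose scales differ by orders of magnitude.
   Trees are scikit-learn decision trees; the stratified bootstrap, OOB
   bookkeeping and permutation importance are computed in this package
   because the library's permutation importance is not out-of-bag. Defaults:
   500 trees, √p features per split, unlimited depth, stratified bootstrap
   preserving class counts. Features are canonicalized to lexicographic
   metabolite-id order before fitting and a single seeded RNG drives
   bootstraps, tree seeds and permutations, so the ranking is invariant to
   input column order; importance ties break by metabolite id. The top 30
   are taken and features without identified structures dropped (they cannot
   become clinical assays), survivors keeping their original ranks.

5. **Combination search.** Within one metabolic sub-pathway candidate
   markers co-vary, so a panel drawn from a single pathway adds little
   beyond its best member. The search enumerates all size-3 subsets of the
   candidates with at most one marker per sub-pathway (≤ C(19,3) = 969
   fits — exhaustive enumeration replaces irreproducible manual trial and
   error) and ranks them by false negatives on the pretreatment cases,
   then cross-validated Q², then R²Y, then marker ids — a total order, so
   the result is deterministic. False negatives are counted by
   resubstitution by default (a CV mode is available). Established clinical
   markers can be excluded by id so the search must find *new* panels; they
   are fitted separately as the comparison baseline.

6. **OPLS-DA predictive-value model.** Marker intensities are z-scored with
   fitting-cohort statistics, the class response is the centered ±1 dummy,
   and orthogonal projections to latent structures splits X into one
   predictive component plus `k_ortho` components orthogonal to y:
   w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, w_o ∝ p − (wᵀp)w,
   t_o = Xw_o, deflate X by t_o p_oᵀ, repeat, then refit the predictive
   component. The per-marker coefficients b (with t = Xb on the original
   standardized matrix) are the published "constants" (α, β, γ for a
   three-marker panel); the predictive value of a sample is the dot product
   of b with its standardized intensities, and the decision cutoff is 0 —
   strictly positive calls high-risk, a boundary score of exactly 0 is
   negative. Sign indeterminacy is resolved by forcing the response loading
   q > 0 (case scores positive), making coefficients bit-stable across
   runs. If the data carry fewer orthogonal directions than requested,
   extraction stops early and the model records the count used.

7. **Validation.** R²Y = 1 − SS_res/SS_tot on the fitting data;
   Q² = 1 − PRESS/SS_tot from stratified 7-fold cross-validation in which
   the standardization is refit inside every training fold and held-out
   samples are transformed with the training fold's statistics — no
   leakage. Fold assignment shuffles lexicographically sorted sample ids
   with a seeded RNG and deals round-robin within each class, so each
   training fold keeps both classes and the assignment is reproducible.
   Significance comes from a 100-permutation test that reruns the whole
   pipeline under shuffled labels; p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm+1),
   the +1-smoothed estimator whose floor at 100 permutations is 1/101.

8. **Follow-up evaluation.** During/after-treatment samples are scored with
   the model *frozen* on the pretreatment cohort (stored standardization
   stats, stored coefficients — nothing refit) and cross-tabulated against
   the residual-tumour label in a 2×2 table. Sensitivity tp/(tp+fn) and
   specificity tn/(tn+fp) are exact rationals rounded to three decimals for
   reporting; an empty denominator is flagged undefined, never reported as
   zero. Follow-up samples from one subject count as independent evaluation
   units by default (matching how such follow-up tables are reported); a
   per-subject aggregation mode is available. Panel comparison reports both
   tables plus the discordant-sample list — the samples one panel catches
   and the other misses.

## Choices where the design was genuinely open

- **k_ortho = 1** by default: standard for two-class OPLS-DA on a small
  marker panel; configurable. An auto mode could grow k_ortho while Q²
  improves, but with 2–4 markers one orthogonal component is almost always
  the rank limit.
- **Q² denominator** uses the globally centered response; residuals are
  taken against the training fold's centering. This is the common
  chemometrics convention; alternatives differ only in O(1/n) terms.
- **Permutation shuffles that break CV stratification** (a fold losing a
  class, possible at tiny n) score as Q² = −∞ rather than aborting the
  test — conservative for the p-value.
- **Resubstitution FN counting** during combination selection matches how
  an "all cases positive" claim is naturally made on a fitting cohort; the
  CV-based count is one flag away.

## The synthetic-cohort generator

No patient-level data are distributed with the study this pipeline
operationalizes, so the generator is the test bed: it emulates the
*statistical* structure of the cohort and stores everything it planted.

- **Design:** 15 cases / 39 controls, 998 metabolites, one pretreatment
  sample per subject; a follow-up set of 33 during/after-treatment samples
  from 13 case subjects, 13 residual-positive / 20 residual-negative.
- **Noise model:** per-metabolite log-location drawn once (N(3, 1) in
  natural log), intensities log-normal around it with σ_log = 0.5. A skewed
  positive model is required — these data defeat parametric normalization —
  and log-normal is the simplest with the right tails. No within-group
  variance is published; σ_log = 0.5 gives the screen high power at
  fold ≥ 2 while leaving the weakest published folds (0.77) only partially
  detectable, which matches the qualitative picture of a screen that needed
  downstream refinement. It is the generator's main calibration knob and is
  exposed in the config.
- **Planted markers:** the 19 published candidate metabolites at their
  published fold-changes (0.29–31×), case rows multiplied by the fold
  (folds < 1 encode decreases), pathway annotations attached.
- **Exogenous metabolites (64):** elevated (fold U(3,15)) in a random ~70%
  of case samples — drugs follow diagnosis, which is exactly why the
  exclusion stage exists. With no planted markers the cohort is a clean
  null: an undiseased cohort is untreated, so no drug elevation either.
- **Unknown-structure features (11):** planted with strong folds so they
  compete for top forest ranks and the top-30 → 19 exclusion does real work.
- **Dilution:** per-sample factor U(0.5, 2) multiplies the row and is
  recorded as the sample's osmolality, so normalization is exercised and
  recovery is checkable to machine precision.
- **Follow-up:** residual-positive samples keep the planted folds
  geometrically attenuated (fold^a, a ∈ [0,1]); negative samples revert to
  the control distribution. The analysis drivers use a = 0.8 (partial
  response under therapy); the generator default is 1.0.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: between-metabolite correlation beyond the
constructed within-pathway fixtures, age/sex covariate structure, batch and
platform effects, censored (truncated) nondetect mechanisms, and any
relationship between stage or tumour site and marker levels. Tests passing
here show the *procedure* is correct and well-calibrated under its stated
assumptions, not that the published panel generalizes clinically.

## Numerical notes

- Exact Wilcoxon mode switches at combined n = 12 / any tie; the underlying
  distribution comes from scipy, the policy and the rank-sum statistic from
  this package, and tests check the exact branch against brute-force
  enumeration over all group assignments.
- Degenerate inputs: all-identical Wilcoxon input → p = 1 (logged);
  zero-variance column at standardization time → error naming the
  metabolite; orthogonal-component extraction stops when the candidate
  weight norm falls below 1e-10 of the loading norm.
- Latent-vector orthogonality (t ⟂ t_o) holds to 1e-8 relative; the
  coefficient path reproduces component-projection scores to 1e-10; with
  k_ortho = 0 the model equals closed-form PLS1 to 1e-10.
- All randomness (generator, forest, CV folds, permutations) flows from
  integer seeds through `numpy.random.default_rng`; same seed, same bytes.

## Problem sizes

Tests and drivers run the full 54 × 998 cohort for the screen and ranking
stages; model-level simulations (null calibrations, permutation-p
uniformity) use 54 × 3 marker matrices with 100–200 replicates, which is
where those statistics are actually defined. The combination search is
exercised exhaustively on up to 20 candidates (448 constrained fits).

## Known limitations

- The published cohort's own numbers (R² = 0.726, Q² = 0.687, constants
  0.52/0.39/0.23, the 998→255→191→30→19 counts) depend on the unreleased
  patient data; this package reproduces the *procedure* and its printed
  contingency arithmetic, and demonstrates the same qualitative cascade on
  synthetic cohorts.
- OPLS-DA here is strictly two-class with a single predictive component;
  multi-class variants and S-plot-based variable selection are out of scope.
- The cutoff is fixed at 0 by design; ROC-based threshold optimization is
  deliberately not implemented.
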