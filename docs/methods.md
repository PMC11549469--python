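# Methods

This note documents the statistical model implemented by `braincog`, the
synthetic cohort generator used to exercise it, and the numerical and
design choices a user or reviewer would want spelled out.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Canonical two-block PLS

The core object is a sequence of covariation modes between a brain block
`X (n × p)` (e.g. regional sulcal widths) and a cognition block
`Y (n × q)`.  Mode `k` is the pair of unit weight vectors
`(u_k, v_k)` maximizing `cov(X u, Y v)` on the current residual blocks —
computed as the leading singular pair of the deflated cross-covariance
matrix, with the covariance reported as `s₁/(n−1)` on standardized
inputs.  After each mode both blocks are deflated by regression on their
own score (the *canonical* variant: symmetric deflation), so score pairs
from successive modes are mutually orthogonal within each block.  A
brute-force maximization over random unit pairs with alternating
refinement, an explicit SVD oracle, and scikit-learn's canonical PLS all
serve as independent cross-checks in the test suite; the implementation
itself is a direct SVD iteration.

**Loadings** are Pearson correlations between each *original*
(undeflated, standardized) measure and its block's latent score.  This
is the convention of the brain–behaviour PLS literature; an alternative
(regression loadings from the algorithm's deflation step) exists, and the
choice is deliberately pinned here because the two differ beyond mode 1.

**Sign convention.**  The SVD determines each weight pair only up to a
joint sign.  Each mode is deterministically flipped so that the mean
brain loading is non-negative — higher brain projections mean wider
sulci, and (because the two blocks' signs are tied through the mode)
higher cognitive projections then track the same latent direction.  Ties
(mean loading exactly zero) break toward no flip.

**Projection of held-out subjects** applies the stored weights *and* the
stored deflation operators sequentially, so projecting the training data
reproduces the stored scores exactly and clinical (MCI/AD) subjects can
be scored through a model trained on healthy participants only.

## Preprocessing

Fixed stage order: orient → hemisphere-average → sparse-feature drop →
harmonize → impute → (optional) residualize → standardize.  The order is
a design decision: harmonization sees only observed values, and
imputation happens at the modelling stage.

* **Orientation**: each cognitive test carries a `positive`/`negative`
  tag; negatively-oriented scores (error rates, reaction times) are
  negated so that more positive always means better performance.
* **Hemisphere averaging**: `<base>_left` / `<base>_right` label pairs
  are averaged into `<base>`; if one side is missing the available side
  is used; unpaired labels pass through unchanged.  A 127-label atlas
  with 63 bilateral pairs and one left-only structure yields 64 unique
  measures.
* **Sparse features**: features missing in strictly more than 50% of
  subjects (configurable) are dropped, and the removal list reported.
* **ICV correction** for volumes: `hv / icv × mean_icv`, invariant to a
  common rescaling of all ICVs.
* **Imputation** replaces missing entries by the mean over the declared
  fitting cohort; observed entries are never altered.
* **Residualization** (used for the pooled healthy+clinical analysis)
  removes per-feature least-squares `intercept + age + sex` predictions,
  with coefficients learned on the fitting cohort.  Sex is coded
  0 = male, 1 = female throughout.
* **Standardization** centers and scales by fitting-cohort mean and
  *sample* sd (ddof = 1).  Zero variance on the fitting cohort is a hard
  error (surfacing degenerate inputs rather than silently rescaling).

All parameters are learned on an explicit `fit_ids` subset and reused
verbatim on held-out subjects.

## Site harmonization (parametric ComBat)

Per feature, a least-squares model with site indicators (constrained to
a weighted zero sum, giving the grand intercept) plus covariates (age,
sex, MCI/AD indicators) is fitted on complete cases; residuals are
standardized by the pooled residual sd; per-site location and scale are
shrunk by empirical Bayes (normal prior for locations, moment-matched
inverse-gamma for scales) via iterative conditional estimation to a
relative tolerance of 1e-4.  The adjusted value is
`pooled_sd · (z − γ*)/√δ* + α + Xβ`.  Choices worth noting:

* Parametric priors — the canonical genomics formulation, matched
  against the Bioconductor reference implementation (`sva::ComBat`) to
  < 1e-6 in a test.
* Missing data: per-feature complete-case fitting, adjustment only where
  observed; missingness is never altered.  This is the minimal extension
  of the complete-data formulation.
* Sites with ≤ 3 subjects are excluded (with a warning); a single
  remaining site makes the model the identity.
* Diagnosis enters as MCI/AD indicators against the HC reference.
* Only the brain block is harmonized; cognition is not.
* `eb=False` (raw per-site estimates) reproduces exact per-site
  standardization and is used for closed-form checks, not for analysis.

## Mode and loading inference

**Permutation test.**  Rows of the cognition block are shuffled
(`n_perm` = 1000 by default), PLS is refitted, and the covariance of the
*first permuted mode* is recorded.  Every observed mode is compared to
this same null — the first permuted mode extracts the most covariance a
null sample can offer, making it the strictest available reference.
`p = (1 + c)/(n_perm + 1)` (add-one rule: p is never 0, and the smallest
reportable value at 1000 permutations is 1/1001, i.e. "p < 0.001"); a
z-scored covariance `(cov − mean_null)/sd_null` is reported alongside.
A mode is called robust at p < 0.05.

**Bootstrap.**  Subjects are resampled with replacement (`n_boot` = 1000
by default) and the *full* fit — imputation, standardization, PLS — is
re-run inside each resample.  The resampled mode is matched to the
original by the largest absolute weight-vector similarity among the
first three modes (sum of within-block dot products) and sign-aligned
before accumulation; this alignment is not part of the classical recipe
but is required to avoid sign-flip and mode-swap artifacts, and the
similarity is deliberately computed per block so results are invariant
to a global sign flip of either data block.  A feature is reliable when
its 2.5 and 97.5 percentile loadings share a sign.  Resamples producing
a zero-variance feature are redrawn (≤ 10 attempts, counted).

## Covariate statistics

* Age: OLS slope of the projection on age, two-sided Wald t-test.
* Group effects (sex; diagnosis; amyloid; APOE ε4; education): linear
  model `projection ~ covariates + group`, with the group factor tested
  by the nested-model F (equal to the Type-II test for a single factor).
  Sex is tested controlling for age; the others controlling for age and
  sex; extra continuous covariates (e.g. a polygenic risk score) can be
  added to the covariate list.
* Age-by-group interaction: `projection ~ covariates + group + age +
  group×age`, interaction block tested against the additive model.
* One member of each twin pair (lexicographically larger subject id) is
  removed before any ANCOVA — deterministic and auditable.
* Amyloid status: positive iff centiloid strictly > 20; exactly 20 is
  negative (the printed rule is strict on the positive side; the
  boundary itself is a package decision).
* Education split: above/below the median of *healthy* participants;
  ties go below.
* Multiplicity: Bonferroni over a declared family of tests, default
  `n_tests = 14` (0.05/14 ≈ 0.00357 < 0.004).  The family size is a
  config parameter because the membership of the family is
  study-specific.

## Model criticism

**Surrogate modes.**  Each surrogate permutes the assignment of fitted
first-mode weights to features, independently within each block (both
blocks permuted per surrogate), recomputes the projections and
re-evaluates a statistic (age slope of either projection, or a group
mean difference computed on the cognitive projection).  The original
statistic's two-sided add-one rank among surrogates gives p.  A known
limitation: the fitted mode's projection has slightly larger variance
than weight-permuted surrogates (the weights are optimized for the data
at hand), so at small n and feature counts the null p-values are mildly
anti-conservative; at the scales used for calibration checks here
(n = 200, 30 × 20 features) the null distribution is uniform to KS
precision.

**Classification.**  A linear soft-margin SVM (C = 1, no tuning)
classifies healthy vs clinical participants from projection scores under
stratified 10-fold cross-validation; features are standardized within
each training fold; ROC AUC is computed per fold from decision values on
the held-out fold and averaged over folds (fold-averaged rather than
pooled — the alternative was open and this choice is pinned).

## Synthetic cohort generator

The generator produces the structure the analysis assumes, with full
ground truth:

* a per-subject latent score `l = β_age·z(age) + β_sex·female +
  β_MCI + β_AD + β_amyloid·Aβ⁺ + N(0,1)`;
* brain features `baseline + mode_strength·√p·l·w_brain + γ_site +
  δ_site·N(0,1)` — the same additive/multiplicative batch model the
  harmonization stage assumes; cognition analogously with a negative
  sign (positive = better) plus an education term;
* unit-norm planted weight vectors drawn `N(0.5, 1)` before
  normalization: predominantly positive (the latent process widens most
  sulci and lowers most scores, making the mean-loading sign convention
  meaningful) while keeping enough spread for informative recovery
  checks.  The `√(n_features)` factor makes `mode_strength` the average
  per-feature signal-to-noise in standardized units;
* ages uniform on the configured range (49–73 by default, a mid-life
  range; only ranges, not shapes, are typically reported); 74% female;
  sites assigned round-robin then shuffled so every site has > 3
  subjects; diagnosis fractions configurable (10% MCI, 5% AD default);
  centiloid drifting upward with age and disease stage; education
  integer-valued around 13 ± 3 years; 3.5% missing completely at random
  by default.

What the generator does **not** emulate: residual correlation among
cognitive tests beyond the shared mode (tests are conditionally
independent given the latent — real batteries share method variance);
site-by-age confounding (available in dedicated harmonization fixtures
but not the default cohort); longitudinal structure; non-MCAR
missingness; floor/ceiling effects in test scores.  Passing tests
therefore demonstrate correctness of the machinery under the stated
generative model, not robustness to those real-data features.

Recovery checks compare fitted weights with the planted direction
*mapped into the standardized analysis basis* (`w_true/sd` per feature,
then correlated): per-feature standardization deterministically shrinks
high-signal features, so a raw-basis correlation would mix that basis
change into what should be an estimation-error measure.

## Numerical choices and degenerate inputs

* Standardization and covariances use sample statistics (ddof = 1).
* SVD sign indeterminacy is resolved deterministically (largest-|entry|
  element of the left vector positive) before the loading-based flip.
* Rank is estimated from singular values at a 1e-10 relative tolerance;
  requesting more modes than the rank is an error.
* Permutation nulls with zero spread, blocks with non-finite entries,
  confounded ANCOVA designs, unknown sites at apply time, and feature
  blocks with duplicate labels all raise typed errors rather than
  propagating NaNs.
* Pipeline runs are byte-reproducible: all stage seeds derive from the
  single config seed and are logged together with the config hash.

## Problem sizes

Calibration and power checks in the test suite and acceptance script use
200 replicate null cohorts (n = 200, 30 × 20 features, 199 permutations)
for the type-I rate, n = 500 for mode recovery, 100 replicates (n = 300,
3 sites) for harmonization, 50 cohorts × 200 bootstrap resamples for
loading reliability, 1000 surrogates on planted cohorts plus 100 null
replicates for the surrogate test, and 50 replicates for classification
ordering — sizes at which each property's sampling error is small
relative to the margin being asserted, while the whole suite stays
lightweight.
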