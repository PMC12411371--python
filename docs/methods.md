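# Methods

## Concordance correlation coefficient

For paired measurements x, y of the same quantity on the same subjects,
Lin's concordance correlation coefficient is

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

where all moments are **population** moments (divide by n). The population
convention follows the original estimator; sample (divide by n−1) moments
change values noticeably at small n, so the choice is stated explicitly
and frozen. rho_c is symmetric, invariant under a common additive shift of
both vectors, bounded by the Pearson correlation in absolute value, and
equals 1 only for exact agreement.

**Degenerate input.** When both vectors are constant and equal the
denominator is exactly zero and the CCC is undefined. The implementation
returns NaN (an explicit undefined sentinel) instead of raising: constant
features occur routinely in synthetic edge cases and a single degenerate
feature must not abort a multi-repeat sweep. Undefined features are
excluded from threshold partitioning (counted in `n_undefined`) and from
averaging (dropped and logged). Missing values, by contrast, are rejected
at validation — no pairwise deletion; the replicate design is complete-case
by construction.

**Aggregation.** Repeat-level values are summarized as mean ± z·sd/√k with
the sample sd (k−1 denominator) and the normal quantile z for the chosen
level (1.96 at 95 %). The normal approximation was chosen over a bootstrap
because it is deterministic given the repeat values and adequate at the
k = 100 repeats used throughout; with k = 1 or zero variance the interval
collapses to the mean.

## The house/room ("elephant") simulator

Each of n houses either contains exactly one elephant (label 1) or none
(label 0). An occupied house's elephant sits in one of R rooms; the room
indicator matrix is observed at two timepoints.

- **Prevalence is an exact count**: round(p·n) houses are occupied, with
  random placement. This guarantees both classes are present whenever
  0 < p < 1 and n ≥ 2, making the OR-rule AUC = 1 property unconditional
  rather than probabilistic.
- **Movement law**: at each timepoint the occupied room is drawn uniformly
  and independently — the elephant may stay put. This law admits a closed
  form for the per-room CCC: for room j, Cov(X1_j, X2_j) = p(1−p)/R² and
  Var(X_j) = (p/R)(1 − p/R), with equal means, giving

      rho_c = (1 − p) / (R − p),

  e.g. 0.2 at R = 3, p = 0.5. A `forced_move` flag draws the second room
  uniformly from the R−1 other rooms instead (no closed form used; off by
  default).
- **One elephant per house** is enforced as an invariant: every row sum of
  both indicator matrices equals the label.
- **Sample-size sweep**: for each cohort size, `repeats` independent
  cohorts are simulated under derived seeds; the per-repeat statistic is
  the mean of the per-room CCCs (rooms averaged first, then mean ± CI
  across repeats). Undefined per-room CCCs are dropped and counted.

## Synthetic replicate-study generator

The generator emulates a feature panel measured twice on training subjects
(two nearby image slices standing in for scan/rescan) and once on test
subjects, with a binary outcome. Per subject i and feature f:

    x_{i,f}^{(rep)} = s_{i,f} + e_{i,f}^{(rep)},  e ~ N(0, 1 − r_f) iid per replicate
    s_{i,f} = sqrt(r_f) · t_{i,f},                Var(t) = 1

so each feature has unit marginal variance and theoretical CCC equal to
its reliability target r_f ∈ [0, 1] (replicate means are equal by default;
a `replicate_shift` option adds a systematic offset to replicate 2, which
lowers the CCC without touching the correlation). The stable latent t
mixes a feature-specific Gaussian with one of `n_factors` shared factors
at weight `factor_strength` (defaults 5 and 0.3), giving the mild
background correlation typical of real feature panels. Gaussianity
throughout is the minimal assumption that makes the CCC = reliability
identity exact and testable.

Default panel: 100 features with reliabilities evenly spaced on
[0.05, 0.95]; training n = 300 with two replicates, test n = 150 with one;
balanced classes with exact counts.

**Signal placement.** A latent z_i = N(0, 1) + effect_size · y_i (default
effect_size 2, i.e. a two-SD class separation on z) is injected with
amplitude `signal_scale` (in units of the features' unit SD):

- `concentrated`: signal_scale·z is added to the *stable* component of the
  `n_carriers` (default 3) **highest**-reliability features. The signal is
  shared between replicates, so carrier CCCs rise even further.
- `distributed`: for every subject and **every replicate independently**,
  one of the `n_carriers` **lowest**-reliability features is chosen
  uniformly and signal_scale·z is added to its observed value — the
  continuous elephant mechanism. The carrier sum contains z exactly once
  per replicate and stays informative, while each carrier's CCC is diluted
  to roughly (r + a²σ_z²/m²) / (1 + a²σ_z²/m) for amplitude a and m
  carriers, well below common thresholds.
- `null`: no injection; labels are independent of all features.

`signal_scale` defaults to 3.0, fixed from the closed-form AUC of the
carrier-sum statistic, Φ(a·δ / sqrt(2(a² + m))) ≈ 0.89 at a = 3, δ = 2,
m = 3: large enough that the distributed regime is decisively predictive
in aggregate, while each carrier's CCC stays far below 0.7. The test set
is drawn from the replicate-1 law; in the distributed regime its one-hot
allocation is drawn once, as a single measurement implies.

## Threshold-partition pipeline

Per repeat the pipeline computes the per-feature CCC between the two
training replicate tables; replicate 1 is the modeling table and the test
set is a single measurement.

- **Partition**: a feature is reproducible iff CCC **strictly** exceeds the
  threshold ϑ (matching the common "> 0.70" convention); undefined-CCC
  features join neither side and are counted. Reproducible-set size is
  non-increasing in ϑ by construction. Default grid: 0.60 to 0.95 in steps
  of 0.05.
- **Selection**: features are standardized on the training data and fed to
  an L1-penalized logistic regression; the penalty is chosen by stratified
  5-fold cross-validation (AUC scoring, shuffled folds under a derived
  seed) over a 50-point logarithmic grid of C ∈ [1e−4, 1e4]. Features
  with nonzero coefficients are kept, ordered by |coefficient|. If the CV
  optimum keeps nothing, the fallback walks the grid from the weakest
  penalty and returns the single largest-|coefficient| feature at the
  smallest penalty yielding any nonzero coefficient, so the pipeline never
  silently fits on an empty set; fallback events are logged. Constant
  features are dropped before standardization.
- **Classifier**: a random forest with 100 trees (default impurity split,
  seeded); hyperparameters are deliberately unremarkable. Test scores are
  class-1 probabilities.
- **Metrics**: AUC by the trapezoidal rule over the empirical ROC
  (verified in the tests against a brute-force pairwise win-fraction
  oracle), AUPRC by step-wise precision–recall summation, and F1 /
  sensitivity / specificity at the ROC point maximizing Youden's
  J = sensitivity + specificity − 1, ties broken toward higher
  sensitivity. The operating point is located on the **test-set** scores;
  this is the optimistic reading of "the optimal point of the ROC curve"
  and is flagged as such — thresholded metrics here bound, rather than
  estimate, deployable performance.
- **Sweep bookkeeping**: per repeat a fresh study is generated (or, for a
  fixed study, its training samples — which carry both replicates — are
  stratified-re-split at a default 2/3 train fraction; the repeat-level
  test fold is scored on replicate-1 values). An empty partition side
  (e.g. the reproducible side at ϑ = 0.95 when no reliability reaches it)
  is recorded as missing-value rows, never skipped — dropping those repeats
  would bias the CIs. `all`-features results are computed once per repeat
  and replicated across ϑ for tidy plotting (flagged in the schema).
  Identical feature sets at adjacent thresholds reuse the fitted result,
  which leaves the output bit-identical while saving redundant fits.

## Seeding

A single root seed is used everywhere; every component derives its own
seed by hashing (root, component name, indices) with SHA-256 and taking
32 bits, so draws are reproducible, independent across components, and
stable when new components are added. Re-running any experiment with the
same configuration yields a bit-identical result table.

## Problem sizes used in the checks

The built-in checks run at desk scale, chosen to make the Monte-Carlo
margins decisive: closed-form recovery of the toy CCC at 10,000 houses
(per-room sampling sd ≈ 0.013), generator calibration at n = 5,000 over 50
features, the cohort-size sweep at {15, 50, 100, 200} × 100 repeats, and
the three-regime pipeline comparison with 50 features, n = 300/150 and 20
repeats at ϑ = 0.75, where the observed AUC separations (≈ 0.35–0.4)
dwarf the repeat-level standard errors.

## What the generator does and does not emulate

It reproduces the statistical skeleton of a replicate feature study —
correlated continuous features, a controllable reliability spectrum,
exchangeable replicates, signal either concentrated in reliable features
or distributed across unreliable ones. It does **not** emulate real
image-derived feature marginals (skewness, heavy tails, discreteness),
feature-specific noise structure, block-correlation from filter families,
label noise, or distribution shift between train and test. Passing
pipeline checks therefore demonstrate the *mechanism* — that concordance
filtering can discard distributed signal — not the magnitude of the effect
in any particular real dataset; which regime a real dataset occupies is an
empirical question the package cannot settle.

## Known limitations

- The CCC here is the two-replicate estimator only; no ICC variants,
  analytic standard errors, or >2-replicate designs.
- The Youden operating point on test scores makes F1/sensitivity/
  specificity optimistic by construction (see above).
- Repeated splits of a fixed study reuse its samples, so repeat-level
  results are not independent; CIs for that path describe split-to-split
  variability, not sampling variability.
- The LASSO CV folds and the train/test split are both re-drawn every
  repeat under derived seeds; variability from the two sources is not
  separated.
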