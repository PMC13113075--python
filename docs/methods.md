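# Methods

## The model

Each row of a feature table is one 20-second acoustic sample, nested as
Animal → growth phase → distress condition → recording (60 s) → sample
(3 × 20 s). For every acoustic trait *y* the core model is the Gaussian
linear mixed model

    y_ijkm = β0 + β1·Sex_i + β2·Phase_j + β3·Distress_k
             + u_i + v_im + ε_ijkm

with animal intercepts u_i ~ N(0, σ²_Animal), recording intercepts
v_im ~ N(0, σ²_Recording) nested in animal, and residuals ε ~ N(0, σ²).
Sex, phase and condition are unordered categorical fixed effects with
treatment coding against (female, farrowing, normal); phase is *stored* as
an ordered categorical for reporting only. Estimation is REML via
statsmodels `MixedLM` (the recording level enters as a variance component
over within-animal recording dummies). Model comparisons — block
likelihood-ratio tests, interaction selection, AIC — always refit by
maximum likelihood.

Derived quantities:

* **ICC.** σ²_Animal / (σ²_Animal + σ²) with a single random level;
  σ²_Animal / (σ²_Animal + σ²_Recording + σ²) when the recording level is
  present. A model-free variant (`residual_icc`) takes OLS residuals after
  the fixed effects and applies the unbalanced one-way ANOVA estimator;
  on synthetic data it agrees with the model-based ICC in ordering across
  traits.
* **Marginal / conditional R².** R²m = var_f / (var_f + Σσ²_random + σ²),
  R²c adds Σσ²_random to the numerator, where var_f is the *population*
  (n-denominator) variance of the fitted fixed-effect predictor over the
  analysis rows — the convention for Gaussian mixed models.
* **Drop-one ΔR².** R²m(full) − R²m(full minus one block) for blocks
  {sex, phase, distress}, every reduced model refitted by the same REML
  procedure. Because full and reduced fits are separate optimizations the
  raw difference can be slightly negative; it is clamped at 0 and flagged.
* **Interaction selection.** Distress × phase is retained iff the ML
  likelihood-ratio p < 0.05 *and* AIC decreases. Design cells the study
  never ran (heat stress before growing, thirst in farrowing) make some
  interaction columns zero or collinear with main effects; the estimable
  subset is selected greedily by rank and the dropped cells are reported.
  The joint p-AND-AIC rule has empirical type-I retention of about 4% at
  the default design size (the LRT itself runs at ~6% for nominal 5%, the
  usual mild asymptotic liberality).
* **FDR.** Benjamini–Hochberg step-up across the family of all trait ×
  block tests (one family per `partition_traits` call).

Skewed traits (duration, energy, pitch) are log-transformed before
modeling by default; the generator simulates them log-normally for the
same reason.

## Numerical choices

The REML/ML criterion is optimized by BFGS with gradient tolerance 1e-10,
falling back to CG, then Powell, then L-BFGS, each capped at 200
iterations; a fit that no optimizer converges raises rather than returning
silently. The order matters: L-BFGS as shipped reports convergence at
log-likelihoods up to ~10 units short of the optimum, which would corrupt
likelihood-ratio statistics, so it is the last resort. With the tight BFGS
tolerance the REML components match the closed-form one-way ANOVA
method-of-moments estimator on balanced intercept-only layouts to better
than 1e-6 relative (asserted in tests).

Probability ties in classifier argmax break by the fixed class order
(normal, pain, hunger, thirst, cold, heat). Entropy uses the natural
logarithm (maximum ln 6 ≈ 1.792 for six classes) with 0·log 0 := 0.
The clustering distance is 1 − S (S ∈ [0, 1] makes this a bounded
dissimilarity); the cluster count is chosen at the largest gap in the
merge-height sequence with height 0 prepended, so a flat dendrogram yields
all singletons and a block structure is cut inside its gap.

## Subject-wise cross-validation

Folds partition *animals*, never samples: per fold, train and test animal
sets are disjoint (asserted at fit time), which also keeps whole
recordings together. The fold builder balances animals per fold to within
one and assigns animals largest-first to the fold minimizing the squared
deviation of per-fold class counts from the global proportions
(deterministic under the seed). It is hand-rolled rather than sklearn's
`StratifiedGroupKFold` because equal animal counts per fold (40/5 = 8) are
part of the design contract.

All preprocessing is inside the fold pipeline: numeric features are
imputed with the training-fold median, categoricals with the
training-fold mode, and z-scaling (linear model only) is fitted on
training rows — the imputation leakage contract is unit-tested by
checking the fitted statistic against the two fold medians. Models:
multinomial logistic regression (L2, C = 1, balanced class weights),
random forest (500 trees), histogram gradient boosting (library
defaults); hyperparameters are fixed rather than tuned — nested grouped
search would be the extension point. Tree models see unscaled features.

Balanced accuracy is the unweighted mean of per-class recalls and
macro-F1 the unweighted mean of per-class F1 (0 when P + R = 0), both
computed from the pooled out-of-fold confusion matrix and cross-checked
against scikit-learn in tests.

`run_recordwise_cv` exists only as the leakage comparator: stratified
sample-level folds that split recordings and animals across train/test.

## Permutation importance

Within each grouped test fold the raw feature column is shuffled
(n_repeats = 10 by default) and Δmacro-F1 = baseline − permuted is
averaged per fold; fold means aggregate as mean with empirical 2.5/97.5
percentiles. Shuffling the *raw* column means one-hot groups (sex, phase)
are permuted jointly — permuting dummy columns independently would create
impossible multi-hot rows, so joint permutation is the only coherent
option. Negative importances are reported as-is. Ranking stability is the
mean pairwise Kendall τ between fold-wise importance vectors.

## The synthetic generator

`synthetic_data` emulates the study design: 40 animals (sex split 0.5),
phase-dependent condition availability (farrowing: normal/pain/hunger/
cold; nursery adds thirst; growing and finishing swap cold for heat
stress), one recording per animal × phase × condition cell, three samples
per recording → 2280 rows. Trait values follow the mixed model above;
`log_scale` traits are simulated on the log scale and exponentiated.
Pitch missingness is MNAR in the design factors only: each pitch value is
deleted with probability logistic(intercept + phase + condition), with
coefficients calibrated so missingness is near zero at farrowing, rises
steeply by finishing, and is highest under heat stress and hunger —
missingness does *not* depend on the latent pitch value given the
factors, which is one respect in which the generator is milder than real
pitch-tracking failure. One `numpy` Generator seeded once is consumed in
fixed design order, so equal seeds give bit-identical tables.

Default effect sizes (`data/default_config.yaml`) are calibrated
*qualitatively* to the study's descriptive pattern — pain loud and
F2-elevated, cold long, heat high-pitched and short — not fitted to data.
What passing tests on this generator show is that the estimators recover
known structure of the assumed model; they cannot certify behavior under
real-data violations (non-Gaussian residuals beyond log-normality,
value-dependent missingness, label noise, farm acoustics).

Because the study deposited only cell-level summaries, `datasets`
embeds its design counts and per-condition trait moments and
`synthetic_study_table()` builds a sample-level stand-in whose cell
counts, pitch-missing counts and per-condition means/SDs match those
summaries exactly (standardized exponential quantiles, affinely rescaled;
the bounded standardized minimum keeps positive traits positive). That
table supports count-structure and effect-size computations; it is
synthetic and supports no inferential reanalysis. Recomputing Cohen's d
from the published 2-dp-rounded moments reproduces the published values to
±0.01 (one printed ulp); the cold-vs-normal duration contrast lands at
1.27 vs the printed 1.26 purely from input rounding.

The pitch-missingness odds-ratio model defaults to Firth's penalized
likelihood (hand-implemented Jeffreys-prior score correction; validated
against the add-½ closed form on a saturated 2×2) because phases with
zero missingness create complete separation under plain ML; output always
carries a separation flag, and plain ML remains available. Which
estimator produced any published odds ratios under separation is not
determinable, so those are treated as format, not target.

## Validation experiments (`evaluation`)

* **Parameter recovery**: 20 study-sized datasets with σ²_Animal = 4,
  σ²_Recording = 2, σ² = 4 (ICC 0.4); median |σ̂² − σ²|/σ² ≈ 0.15–0.20 and
  median ICC error ≈ 0.03–0.05 at this design size.
* **ΔR² ordering**: generating effects distress > phase > sex; the median
  drop-one ΔR² ranks the blocks identically.
* **Identity leakage**: 20 animals, condition effects scaled to 15%,
  animal and recording variances twice the residual (halved for the
  Gaussian formants, whose positive support caps the spread); record-wise
  minus subject-wise macro-F1 gap ≈ +0.18 in the median, and ≈ 0 when the
  signature variances are removed.
* **Chance-level null**: condition effects zero, availability made
  uniform across phases and missingness switched off (otherwise phase and
  the imputation pattern predict condition base rates); subject-wise
  balanced accuracy sits at 1/6 within Monte-Carlo noise.
* **Interaction operating characteristics**: 20 seeds per arm with the
  recording-nested random spec (dropping it would pseudo-replicate and
  inflate the LRT); a ±5 dB interaction is retained essentially always,
  the null rarely (~4% long-run rate; any single 20-seed window is
  binomial around that).

## Known limitations

Gaussian responses only (no GLMMs); no Bayesian estimation; fixed
hyperparameters without nested tuning; missingness confined to pitch;
confidence intervals for variance components are not reported; the
generator's independence of missingness from latent pitch understates the
difficulty of real pitch dropout.
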