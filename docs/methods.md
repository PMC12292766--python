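# Methods

This note documents the models and procedures implemented in `coxmorph`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not establish.

## Landmark schema and measurement geometry

Every bone is a 34×3 matrix of millimetre coordinates over a fixed,
ordered registry of anatomical landmarks. Coordinates live in an
arbitrary scanner frame: no registration, alignment, or mirroring is ever
applied, because every derived quantity is invariant under rigid motion
and reflection. Three geometric primitives generate all measurements:

- **Euclidean distance** between two landmarks (mm);
- **vertex angle** between the arms `v→a` and `v→b` (degrees in
  [0, 180]); the normalized dot product is clamped to [−1, 1] before
  `arccos` so exactly collinear arms return 0° or 180° instead of NaN;
- **point-to-line height**: orthogonal distance from an apex landmark to
  the *infinite* line through two baseline landmarks (an apex beyond a
  baseline endpoint still projects orthogonally). Coincident baseline
  points and zero-length angle arms raise a degenerate-geometry error
  rather than guessing.

The *first dataset* is a battery of 33 named measurements (27 linear,
3 heights, 3 angles) in a fixed reporting order; the *ILD dataset* is the
canonical enumeration of all 561 unordered landmark pairs, named `a-b`
with `a` preceding `b` in registry order. Angles are reported in degrees
(the reference values, roughly 50–155, are only plausible on that scale).
Measurements are unit tests' ground: rigid/mirror invariance holds to
1e-9 relative, scaling coordinates by *s* scales lengths by *s* and
leaves angles fixed, and each angle agrees with the law of cosines
applied to its three pairwise distances to 1e-6 degrees.

## Missing-landmark imputation

Missingness is landmark-wise: a landmark is present with all three
coordinates or absent entirely. Bones missing more than three landmarks
are outside the supported regime (they are flagged by validation and
rejected by the imputer unless explicitly overridden).

Imputation operates per side on the pooled male+female coordinate matrix
(bones × 102 coordinate scalars). Each scalar coordinate with missing
values is regressed on all other coordinates with a Bayesian ridge model
— a linear model whose L2 shrinkage strength is estimated from the data —
and the algorithm cycles over incomplete columns (descending missing
count, initial fill = column mean) until the relative change of the
imputed values drops below `tolerance` or `max_iterations` is reached.
Defaults: `max_iterations=10`, `tolerance=1e-3`. Observed entries are
returned bit-exactly unchanged.

Two caveats are deliberate and documented rather than hidden. First,
pooling before any train/test split lets imputed test bones borrow
information from training bones; the effect is bounded (at most 3 of 34
landmarks per bone) but strict generalization studies should impute per
split. Second, with fewer complete rows than the 102 predictors the
regressions are rank-deficient; the ridge prior keeps them defined, and a
warning is emitted below 102 complete rows.

## Reliability (TEM / rTEM)

For N subjects with k repeated acquisitions, the technical error of
measurement is the square root of the pooled within-subject variance of
the repeats,

    TEM = sqrt( Σ_i Σ_j (x_ij − x̄_i)² / (N (k − 1)) ),

computed via deviations from each subject's repeat mean (algebraically
identical to the classic Σx² − (Σx)²/k form, but exact when repeats are
identical). The relative TEM is 100·TEM divided by the grand mean of all
N·k values; with balanced data the grand mean equals the mean of subject
means, so the choice between the two denominators is immaterial here.

Reliability is evaluated on the ILD battery only (561 distances per side,
1122 entries for a two-sided study): the named measurements either are
interlandmark distances themselves or are derived (angles, heights) from
the same landmarks, so ILD repeatability bounds the landmark-placement
error that propagates into every measurement. Under isotropic
per-landmark noise of SD σ per coordinate, a well-separated ILD has
repeat SD ≈ σ√2, which TEM estimates; the simulation tests confirm both
the level and its linear scaling in σ.

## Group comparisons

Each measurement is compared between two groups with a test chosen by a
Shapiro–Wilk gate at level 0.05: the parametric test (Welch's *t* for
independent groups, paired *t* for sides) is used only when **both**
groups pass the gate — for paired designs, when the per-individual
differences pass. Otherwise the rank-based alternative (Mann–Whitney U,
Wilcoxon signed-rank) is used. The both-must-pass rule is a declared
choice; requiring only one group to fail gives the same answer in all but
borderline cases. Constant samples, for which the Shapiro–Wilk statistic
is undefined, are treated as passing (they carry no evidence against
normality and arise only in degenerate synthetic inputs).

All tests are two-sided at α = 0.05 with **no multiple-testing
correction**: results are reported per measurement, as is conventional
for descriptive dimorphism tables, and the type-I error of the machinery
is verified by simulation (empirical false-positive rate within
[0.03, 0.07] over 1000 null measurements). Sex comparisons run per side,
side comparisons per sex (paired within individual, right−left), age
comparisons per sex per side around a 45-year cutoff (the conventional
onset of menopause). Signed differences follow male−female, right−left
and young−old conventions.

Feature screening for the classifiers keeps the measurements with
significant sex differences. By default the screen is computed on the
training portion only (leak-free); a flag reproduces full-sample
screening for comparability with workflows that screen before splitting.

## Classification protocol

Models are pipelines of per-feature standardization followed by a linear
classifier: logistic regression (liblinear) with L1 or L2 regularization,
or a linear-kernel SVM. The scaler is a pipeline step, so it is refitted
inside every cross-validation fold and never sees validation data.

- **Splits.** Test sets are fixed-size stratified draws: 50 bones for
  right-only or left-only datasets, 100 for the combined dataset;
  stratification is by sex × age group (≤45 / >45), plus side for the
  combined dataset. Combined splits are bone-level, so the two bones of
  one individual can straddle the boundary; a warning is logged because
  bilateral correlation then leaks some individual-level information.
- **Tuning.** The single hyperparameter C (inverse regularization
  strength / margin trade-off) is searched with 50 seeded log-uniform
  draws from [10⁻³, 10²], each scored by mean accuracy over
  10-times-repeated stratified 5-fold CV on the training set; the winner
  is refitted on the full training set. The 50-draw budget is a package
  choice; the search space and CV scheme are part of the protocol.
- **Reporting.** Training accuracy is the mean over the 50 winning fold
  scores with a normal-approximation 95% CI (±1.96·SE); test metrics are
  accuracy plus per-class precision, recall and F1 — both classes
  reported, no hidden positive class — all as percentages.
- **Feature selection.** Besides L1 sparsity, recursive feature
  elimination with CV is provided: a 100-tree random forest ranks
  importances, one feature is dropped per step, each subset size is
  scored by stratified 5-fold CV accuracy, and the best size wins
  (smallest on ties).
- **Probabilities.** Logistic models are natively probabilistic; the SVM
  maps decision values through a sigmoid calibrated on the training data
  (fitted via internal cross-validation, final margin classifier refitted
  on all training rows). Saved models (joblib + JSON sidecar for
  language-neutral inspection) reload to bit-identical predictions.

On reference-calibrated synthetic cohorts the protocol reaches ≥95% test
accuracy with a train/test gap under a few points, consistent with the
strong dimorphism encoded in the preset (many measurements differ by
~2 pooled SD between sexes).

## Synthetic cohorts

Because the underlying CT cohort is not publicly deposited, the package
ships a reference preset — per-measurement means, SDs and ranges for each
sex and side, right−left mean differences, and age-group differences for
an adult Bulgarian sample of 136 males and 140 females (ages modelled as
truncated Gaussians: males 56.5 ± 14.8 in [19, 83], females 56.7 ± 13.8
in [19, 88]) — and generates cohorts at two levels.

**Measurement level.** Bone vectors are drawn from the sex/side Gaussian
with an exchangeable cross-measurement correlation ρ = 0.3 (pairs
involving an angle use ρ/2; the matrix is checked for positive
definiteness and ρ shrunk if needed). The two sides of one individual
share a latent vector with between-side correlation 0.9 — a synthetic
assumption reflecting the strong bilateral correlations reported for
coxal measurements. With the laterality preset on, side means are
rebuilt as (side average) ± (reference right−left difference)/2, so the
population side difference matches the preset exactly; the age preset
likewise splits its offsets ± d/2 around the 45-year cutoff, with the
older group larger where the reference difference is positive (the
prose of the source tables: nearly all significant age effects favour
the older group). True covariance and asymmetry structure of the real
cohort is unpublished; none of these correlations are claims about it.

**Landmark level.** For each sex and side a 34-point *template* is
calibrated by deterministic least squares: the 102 free coordinates
minimize the squared relative deviations of the 33 derived measurements
from the preset means, with a soft hinge keeping every landmark pair at
least 13 mm apart (which bounds rTEM away from blow-up on short
distances; the closest genuinely measured pair, the pubic symphysis
width, is ~15 mm) and a weak pull toward a hand-built anatomical
starting configuration. An analytic Jacobian makes the fit run in
seconds; achieved residuals are ~1e-6 relative, far inside the 1%
acceptance tolerance, and templates are cached per sex/side. Individuals
are then sampled by a global scale factor ~ Normal(1, 0.03²) shared
across sides plus independent isotropic per-landmark jitter (default
1.5 mm); repeat studies add acquisition noise (default 0.3 mm); and
missingness masks 1–3 whole landmarks on a configurable number of bones
(default 35 of 552).

What passing tests show — and do not. The generators guarantee the
*statistical* structure the analysis assumes (marginal means/SDs, side
offsets, dimorphism signs such as the four female-larger measurements
emerging from the preset alone, noise propagation into TEM); they do not
reproduce anatomical shape covariance, non-Gaussian tails, observer bias,
or population structure. Accuracy figures on synthetic cohorts therefore
validate the pipeline's machinery and its behaviour at the declared
effect sizes, not the field performance of any model on real bones.

## Numerical choices and degenerate inputs

- Dot products are clamped before `arccos`; heights use the infinite
  line; degenerate geometry errors out instead of guessing.
- TEM uses the deviation form (exact at zero noise); rTEM requires a
  positive grand mean.
- The template optimizer raises a calibration error with a residual
  report if any measurement misses its target by more than 1%.
- Landmark CSVs are written in shortest round-trip float repr and read
  with a round-trip parser, so write→read is bit-identical.
- Stage seeds in the pipeline are derived from the global seed by
  hashing the stage name, so adding a stage never shifts another stage's
  stream.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at the study's own scales
where that is cheap (276-individual cohorts, 30×3 reliability studies,
50-bone test splits, 10,000-bone means for round-trip checks) and at
reduced replicate counts where a full sweep adds nothing (e.g. 3 seeded
runs for RFECV recovery, 5 seeds for the accuracy floor median). Each
reduction is noted at the assertion it affects.

## Known limitations

- Imputation pools sexes and is fitted once per side; no
  bilateral-symmetry or surface-based reconstruction is attempted.
- The exchangeable-ρ covariance is a simplification; classifiers tuned
  on it may be optimistic relative to anatomically correlated features.
- No multiple-testing correction and no effect-size indices in the
  comparison tables (by design, for parity with descriptive dimorphism
  reporting).
- Single-observer reliability only; interobserver designs and
  Bland–Altman analysis are out of scope.
- Combined-dataset splits are bone-level (see the leakage warning).
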