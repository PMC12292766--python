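# coxmorph

Landmark-based morphometrics of the human coxal (hip) bone, built around a
machine-learning sex-estimation workflow for forensic and biological
anthropology.

The coxal bone is the most sexually dimorphic element of the human
skeleton: the female pelvis must accommodate childbirth, so its greater
sciatic notch is wider and more obtuse, its ischiopubic ramus longer and
more oblique, while nearly every other male dimension is absolutely
larger. `coxmorph` turns 3D coordinates of 34 named anatomical landmarks
per bone into quantitative sex estimates, covering the full chain a
practitioner needs:

- **landmarks** — the fixed 34-landmark schema (`mla`, `iit`, `sps`, …),
  long-format CSV I/O, MeshLab PickedPoints (`.pp`) import, validation;
- **measure** — two measurement batteries per bone: 33 named measurements
  (27 Euclidean distances, 3 vertex angles in degrees, 3 point-to-line
  heights) and all C(34,2) = 561 interlandmark distances (ILDs);
- **impute** — missing-landmark completion by iterative conditional
  regression with Bayesian ridge models over the cohort's 102-column
  coordinate matrix (for bones missing up to 3 landmarks);
- **reliability** — intraobserver error via the technical error of
  measurement, TEM = √( Σᵢ Σⱼ (xᵢⱼ − x̄ᵢ)² / (N(k−1)) ), and
  rTEM = 100·TEM/grand mean, over the ILD battery of repeated
  acquisitions (1122 entries for a two-sided study);
- **stats** — Shapiro–Wilk-gated group tests (Welch's *t* / Mann–Whitney
  U for sex and age groups, paired *t* / Wilcoxon signed-rank for
  right–left laterality) with per-measurement descriptives;
- **classify** — sex classifiers (logistic regression with L1 or L2
  regularization, linear-kernel SVM) in a standardize-then-classify
  pipeline: stratified train/test splits (50 test bones per side, 100
  combined), seeded log-uniform search of the regularization parameter C
  over [10⁻³, 10²] scored by 10×5-fold cross-validated accuracy,
  significance-screened features, optional RFECV feature selection with a
  100-tree random forest, persistence with probability prediction;
- **synthetic** — calibrated synthetic cohorts at two levels: measurement
  vectors drawn from sex/side-specific multivariate Gaussians matching a
  shipped reference preset (adult Bulgarian cohort, 136 males / 140
  females), and landmark-level bones sampled from 34-point templates
  optimized so their derived measurements hit the preset means;
- a `coxmorph` CLI and a one-command end-to-end replication pipeline.

## Worked example

Train and evaluate a right-side linear-SVM sex model on a synthetic
cohort calibrated to the reference preset:

```python
from coxmorph import classify, stats, synthetic

table = synthetic.generate_measurement_cohort(synthetic.CohortConfig(seed=42))
train, test = classify.stratified_split(
    table, classify.SplitSpec("right_only", seed=42))

features = classify.screen_features(train)      # sex-dimorphic measurements
model = classify.tune_and_fit(
    train, classify.ModelSpec("svm_linear"), seed=42, features=features)
metrics = classify.evaluate(model, test)
print(len(features), round(model.C, 3), metrics["accuracy"],
      metrics["recall_M"], metrics["recall_F"])
```

This prints `27 7.409 98.0 96.0 100.0`: 27 of the 33 measurements pass
the significance screen on the training bones, the tuned margin
parameter is C ≈ 7.4, and the model classifies 49 of the 50 held-out
bones correctly (male recall 96%, female recall 100%). Training accuracy
is 98.9% (95% CI 98.5–99.3%), so the model generalizes without
overfitting — test and training accuracy differ by under one point.

The same protocol is available from the shell:

```sh
coxmorph simulate --level measurements --seed 42 --out cohort.csv
coxmorph train --in cohort.csv --scope right --algo svm_linear --seed 42 --out model.joblib
coxmorph predict --model model.joblib --in cohort.csv --proba --out predictions.csv
```

and the whole pipeline (simulate → impute → measure → compare → train →
evaluate) runs from one config with `coxmorph run --seed 1 --out rundir`.

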