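"""Sex-estimation classifiers: stratified splits, tuning, selection, metrics.

The modeling protocol mirrors standard practice for metric sex estimation:

* bones are split into training and test sets, stratified by sex and age
  group (and side, when right and left bones are combined), with a fixed
  number of test bones (50 per single-side dataset, 100 combined);
* only measurements showing significant sex differences enter the models;
* each model is a pipeline of per-feature standardization (fitted on
  training folds only) followed by a linear classifier — logistic
  regression with L1 or L2 regularization (liblinear) or a linear-kernel
  SVM;
* the single regularization hyperparameter C is tuned by seeded
  log-uniform random search over [1e-3, 1e2] (50 evaluations), scored by
  mean accuracy over 10-times-repeated 5-fold stratified CV;
* an alternative feature-selection route uses recursive feature
  elimination with 5-fold CV and a 100-tree random forest importance
  ranking;
* metrics (accuracy; per-class precision, recall, F1) are percentages.

Combined right+left datasets are split at the bone level, so the two
bones of one individual can straddle the train/test boundary; a warning
is logged because bilateral correlation then leaks some individual-level
information into the test set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import stats
from .measure import META_COLUMNS, measurement_columns

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "FittedSexModel",
    "stratified_split",
    "screen_features",
    "tune_and_fit",
    "rfecv_select",
    "evaluate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("lr_l1", "lr_l2", "svm_linear")
DEFAULT_TEST_SIZE = {"right_only": 50, "left_only": 50, "combined": 100}


@dataclass
class SplitSpec:
    """Stratified train/test split settings."""

    dataset_scope: str  # {"right_only", "left_only", "combined"}
    test_size: int | None = None  # default by scope: 50 / 50 / 100
    age_cutoff: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset_scope not in DEFAULT_TEST_SIZE:
            raise ValueError(f"unknown dataset_scope {self.dataset_scope!r}")
        if self.test_size is None:
            self.test_size = DEFAULT_TEST_SIZE[self.dataset_scope]


@dataclass
class ModelSpec:
    """Classifier family and tuning protocol."""

    algorithm: str = "svm_linear"
    c_range: tuple[float, float] = (1e-3, 1e2)
    n_evals: int = 50
    cv_repeats: int = 10
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        lo, hi = self.c_range
        if not (0 < lo < hi):
            raise ValueError("c_range must satisfy 0 < low < high")


@dataclass
class FittedSexModel:
    """A trained standardizer+classifier with its protocol metadata."""

    algorithm: str
    C: float
    feature_names: list[str]
    pipeline: Pipeline
    classes: list[str]
    cv_scores: np.ndarray  # fold accuracies of the winning C, fractions
    training_accuracy: float  # %
    training_accuracy_ci: tuple[float, float]  # %, mean +/- 1.96 SE over folds
    test_metrics: dict = field(default_factory=dict)

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"prediction table lacks feature column(s): {missing}")
        return table[self.feature_names].to_numpy(dtype=float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(self._matrix(table))

    def predict_proba(self, table: pd.DataFrame) -> pd.DataFrame:
        proba = self.pipeline.predict_proba(self._matrix(table))
        return pd.DataFrame(proba, columns=list(self.pipeline.classes_))

    @property
    def coefficients(self) -> pd.Series:
        clf = self.pipeline.named_steps["clf"]
        if isinstance(clf, CalibratedClassifierCV):
            clf = clf.calibrated_classifiers_[0].estimator
        return pd.Series(clf.coef_.ravel(), index=self.feature_names)

    @property
    def dropped_features(self) -> list[str]:
        """Features driven to zero weight (informative for L1 models)."""
        coef = self.coefficients
        return list(coef.index[coef == 0.0])


def _strata_labels(table: pd.DataFrame, scope: str, age_cutoff: float) -> pd.Series:
    lab = table["sex"].astype(str) + "|" + np.where(
        table["age"] <= age_cutoff, "young", "old")
    if scope == "combined":
        lab = lab + "|" + table["side"].astype(str)
    return pd.Series(lab, index=table.index)


def stratified_split(table: pd.DataFrame, spec: SplitSpec
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a measurement table into disjoint train/test tables.

    The test set has exactly ``spec.test_size`` bones and each stratum
    (sex x age group [x side]) is represented proportionally to within
    one bone.
    """
    scope = spec.dataset_scope
    if scope == "right_only":
        table = table[table["side"] == "right"]
    elif scope == "left_only":
        table = table[table["side"] == "left"]
    table = table.reset_index(drop=True)
    if spec.test_size >= len(table):
        raise ValueError(
            f"test_size {spec.test_size} >= available bones {len(table)}")

    strata = _strata_labels(table, scope, spec.age_cutoff)
    counts = strata.value_counts()
    quota = counts * spec.test_size / len(table)
    too_small = counts[(counts < 2) | (counts < np.ceil(quota))]
    if len(too_small):
        raise ValueError(f"strata smaller than their test quota: {dict(too_small)}")

    if scope == "combined":
        n_ind = table["individual_id"].nunique()
        if len(table) > n_ind:
            logger.warning(
                "combined split is bone-level: contralateral bones of one "
                "individual may straddle the train/test boundary")

    train, test = train_test_split(
        table, test_size=spec.test_size, stratify=strata,
        random_state=spec.seed, shuffle=True)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def screen_features(train_table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Measurements with significant sex differences on the given table.

    Applied to the training table by default (leak-free); pass the full
    table to reproduce full-sample screening.  On multi-side tables a
    measurement is kept if it is significant on at least one side.
    """
    comp = stats.compare(train_table, stats.ComparisonSpec("sex", alpha=alpha))
    sig = comp[comp["significant"]]["measurement"].unique()
    order = {m: i for i, m in enumerate(measurement_columns(train_table))}
    return sorted(sig, key=order.__getitem__)


def _make_estimator(algorithm: str, C: float, seed: int, probability: bool = False):
    if algorithm == "lr_l1":
        return LogisticRegression(l1_ratio=1, solver="liblinear", C=C,
                                  max_iter=2000, random_state=seed)
    if algorithm == "lr_l2":
        return LogisticRegression(l1_ratio=0, solver="liblinear", C=C,
                                  max_iter=2000, random_state=seed)
    svc = SVC(kernel="linear", C=C, random_state=seed)
    if probability:
        # Platt-style mapping of decision values to probabilities,
        # calibrated on the training data; the underlying margin classifier
        # is refitted on the full data (ensemble=False).
        return CalibratedClassifierCV(estimator=svc, method="sigmoid",
                                      cv=5, ensemble=False)
    return svc


def _feature_matrix(table: pd.DataFrame, features: list[str] | None
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    features = features or measurement_columns(table)
    X = table[features].to_numpy(dtype=float)
    y = table["sex"].to_numpy(dtype=object)
    return X, y, features


def tune_and_fit(train_table: pd.DataFrame, model_spec: ModelSpec | None = None,
                 seed: int = 0, features: list[str] | None = None
                 ) -> FittedSexModel:
    """Tune C by seeded log-uniform search under repeated stratified CV,
    then refit the winning pipeline on the full training table.

    Standardization is fitted inside each CV fold (the scaler is a
    pipeline step) and finally on the full training set.
    """
    spec = model_spec or ModelSpec()
    X, y, features = _feature_matrix(train_table, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(seed)
    lo, hi = spec.c_range
    candidates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_evals))
    cv = RepeatedStratifiedKFold(n_splits=spec.cv_folds,
                                 n_repeats=spec.cv_repeats, random_state=seed)

    best_c, best_mean, best_scores = None, -np.inf, None
    for C in candidates:
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("clf", _make_estimator(spec.algorithm, C, seed, probability=False)),
        ])
        scores = cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
        if scores.mean() > best_mean:
            best_c, best_mean, best_scores = float(C), scores.mean(), scores

    final = Pipeline([
        ("scale", StandardScaler()),
        ("clf", _make_estimator(spec.algorithm, best_c, seed, probability=True)),
    ])
    final.fit(X, y)

    se = best_scores.std(ddof=1) / np.sqrt(len(best_scores))
    ci = (100 * (best_mean - 1.96 * se), 100 * (best_mean + 1.96 * se))
    return FittedSexModel(
        algorithm=spec.algorithm,
        C=best_c,
        feature_names=list(features),
        pipeline=final,
        classes=list(final.classes_),
        cv_scores=best_scores,
        training_accuracy=100 * best_mean,
        training_accuracy_ci=ci,
    )


def rfecv_select(train_table: pd.DataFrame, seed: int = 0,
                 features: list[str] | None = None,
                 cv_folds: int = 5, n_trees: int = 100) -> list[str]:
    """Feature subset chosen by recursive feature elimination with CV.

    A random forest ranks importances within each CV fold; the subset
    size maximizing mean 5-fold CV accuracy is returned (smallest size on
    ties), then realized by a final elimination pass on the full table.
    """
    X, y, features = _feature_matrix(train_table, features)
    if X.shape[1] < 2:
        return list(features)
    selector = RFECV(
        estimator=RandomForestClassifier(n_estimators=n_trees, random_state=seed),
        step=1,
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        scoring="accuracy",
        min_features_to_select=1,
    )
    selector.fit(X, y)
    return [f for f, keep in zip(features, selector.support_) if keep]


def evaluate(model: FittedSexModel, test_table: pd.DataFrame) -> dict:
    """Test metrics as percentages: overall accuracy and per-class
    precision / recall / F1."""
    extra = [c for c in measurement_columns(test_table)
             if c not in model.feature_names and c not in META_COLUMNS]
    y_true = test_table["sex"].to_numpy(dtype=object)
    y_pred = model.predict(test_table)

    metrics: dict = {
        "accuracy": 100.0 * float(np.mean(y_pred == y_true)),
        "n_test": int(len(y_true)),
        "extra_columns_ignored": extra,
    }
    for cls in model.classes:
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        metrics[f"precision_{cls}"] = 100.0 * precision
        metrics[f"recall_{cls}"] = 100.0 * recall
        metrics[f"f1_{cls}"] = 100.0 * f1
    model.test_metrics = metrics
    return metrics


def save_model(model: FittedSexModel, path) -> None:
    """Persist the model (joblib) plus a JSON sidecar for inspection."""
    path = str(path)
    joblib.dump(model, path)
    sidecar = {
        "algorithm": model.algorithm,
        "C": model.C,
        "feature_names": model.feature_names,
        "classes": model.classes,
        "training_accuracy_pct": model.training_accuracy,
        "training_accuracy_ci_pct": list(model.training_accuracy_ci),
        "test_metrics": model.test_metrics,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path) -> FittedSexModel:
    model = joblib.load(str(path))
    if not isinstance(model, FittedSexModel):
        raise TypeError(f"{path} does not contain a FittedSexModel")
    return model
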