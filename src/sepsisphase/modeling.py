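"""Label construction, model fitting and repeated cross-validated evaluation.

Classification treats adjudication categories 2-5 (early-to-peak phase) as
positive and 1, 6-11 (never septic / recovering / recovered) as negative.
Performance is estimated by repeated stratified 10-fold cross-validation:
each repetition draws a fresh seeded partition, features are z-scored on
the training portion of every fold, and the per-fold metric values are kept
so two models run under the same seed are fold-aligned ("paired") for the
comparison module.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier, AdaBoostRegressor, RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import FeatureMatrix

POSITIVE_CATEGORIES = frozenset({2, 3, 4, 5})

CLASSIFIER_FAMILIES = ("logistic_regression", "linear_svm", "random_forest",
                       "adaboost", "naive_bayes")
REGRESSOR_FAMILIES = ("linear_regression", "svr", "random_forest_regressor",
                      "adaboost_regressor")

#: Feature columns excluded from the SOFA regression because they enter the
#: SOFA criteria directly or proxy one of its organ systems (blood
#: pressures, coagulation, liver, renal, respiration).  8 of the 31 default
#: features, leaving 23 candidates.
DEFAULT_SOFA_EXCLUSIONS: tuple[str, ...] = (
    "systolic_bp", "diastolic_bp", "mean_arterial_pressure",
    "oxygen_saturation", "platelets", "bilirubin", "creatinine", "bun",
)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameter overrides.

    ``calibrate`` wraps margin classifiers (linear SVM) in Platt-style
    sigmoid calibration when probabilities are requested; families that
    already emit probabilities ignore it.
    """

    family: str
    params: dict = field(default_factory=dict)
    calibrate: bool = True

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES + REGRESSOR_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from "
                f"{CLASSIFIER_FAMILIES + REGRESSOR_FAMILIES}")

    @property
    def is_regressor(self) -> bool:
        return self.family in REGRESSOR_FAMILIES


def make_estimator(spec: ModelSpec, seed: int | None = 0, proba: bool = False):
    """Instantiate the scikit-learn estimator behind a ModelSpec."""
    p = dict(spec.params)
    if spec.family == "logistic_regression":
        est = LogisticRegression(max_iter=1000, **p)
    elif spec.family == "linear_svm":
        est = LinearSVC(dual="auto", max_iter=5000, random_state=seed, **p)
        if proba and spec.calibrate:
            est = CalibratedClassifierCV(est, method="sigmoid", cv=3)
    elif spec.family == "random_forest":
        p.setdefault("n_estimators", 100)
        est = RandomForestClassifier(random_state=seed, **p)
    elif spec.family == "adaboost":
        p.setdefault("n_estimators", 100)
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=seed, **p)
    elif spec.family == "naive_bayes":
        est = GaussianNB(**p)
    elif spec.family == "linear_regression":
        est = LinearRegression(**p)
    elif spec.family == "svr":
        p.setdefault("kernel", "linear")
        est = SVR(**p)
    elif spec.family == "random_forest_regressor":
        p.setdefault("n_estimators", 100)
        est = RandomForestRegressor(random_state=seed, **p)
    elif spec.family == "adaboost_regressor":
        p.setdefault("n_estimators", 100)
        est = AdaBoostRegressor(random_state=seed, **p)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.family)
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def binarize_labels(categories: Sequence[int] | np.ndarray | pd.Series) -> np.ndarray:
    """Map adjudication categories to the early-to-peak label: 2-5 -> 1."""
    cats = np.asarray(categories)
    if cats.size and (cats.min() < 1 or cats.max() > 11):
        bad = sorted(set(cats[(cats < 1) | (cats > 11)].tolist()))
        raise ValueError(f"categories must lie in 1..11, got {bad}")
    return np.isin(cats, list(POSITIVE_CATEGORIES)).astype(int)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counting 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s, method="average")
    u = np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def spearman(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size < 3 or a.size != p.size:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(p, a).statistic)


def _decision_scores(fitted, X: np.ndarray) -> np.ndarray:
    model = fitted[-1]
    if hasattr(model, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    return fitted.decision_function(X)


@dataclass
class PairedCVResult:
    """Per-(repetition, fold) metric values for one model.

    ``values`` has shape (repeats, folds) with NaN for skipped degenerate
    folds.  ``fingerprint`` hashes the fold assignments of every
    repetition: two models evaluated with the same seed on the same data
    share a fingerprint, which is the pairing contract the comparison
    module enforces.
    """

    model: str
    metric: str
    values: np.ndarray
    fingerprint: str
    seed: int
    n_skipped: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))

    def long_frame(self) -> pd.DataFrame:
        reps, folds = self.values.shape
        return pd.DataFrame({
            "model": self.model,
            "repeat": np.repeat(np.arange(1, reps + 1), folds),
            "fold": np.tile(np.arange(1, folds + 1), reps),
            "metric": self.metric,
            "value": self.values.ravel(),
        })


def _fold_plan(y: np.ndarray, stratify: bool, repeats: int, folds: int,
               seed: int) -> tuple[list[list[tuple[np.ndarray, np.ndarray]]], str]:
    """Seeded fold partitions plus their pairing fingerprint.

    Derived purely from (seed, repeats, folds, y), never from the model, so
    any two models run under the same seed see identical partitions.
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31 - 1)
    plan = []
    h = hashlib.sha1()
    X_dummy = np.zeros((y.size, 1))
    for r in range(repeats):
        cv = (StratifiedKFold if stratify else KFold)(
            n_splits=folds, shuffle=True, random_state=int(rep_seeds[r]))
        splits = list(cv.split(X_dummy, y))
        for _, test_idx in splits:
            h.update(test_idx.astype(np.int64).tobytes())
        plan.append(splits)
    return plan, h.hexdigest()


def repeated_cv(
    fm: FeatureMatrix,
    spec: ModelSpec,
    metric: str = "auc",
    repeats: int = 50,
    folds: int = 10,
    seed: int = 0,
) -> PairedCVResult:
    """Repeated (stratified) k-fold cross-validated metric estimation.

    Per fold: z-score features on the training portion, fit, score the
    held-out portion, and record the fold metric.  Classification uses
    stratified folds and AUC on decision scores; regression uses plain
    k-fold and Spearman correlation between held-out predictions and the
    actual target.  Degenerate folds (a single class, or a constant metric
    input) are skipped and counted, never silently averaged.
    """
    if metric not in ("auc", "spearman"):
        raise ValueError("metric must be 'auc' or 'spearman'")
    X = fm.X.to_numpy(dtype=float)
    if metric == "auc":
        if fm.y is None:
            raise ValueError("feature matrix has no binary label")
        target = fm.y.to_numpy()
        counts = np.bincount(target, minlength=2)
        if counts.min() < folds:
            raise ValueError(
                f"need >= {folds} patients per class for {folds}-fold "
                f"stratified CV, got counts {counts.tolist()}")
    else:
        if fm.target is None:
            raise ValueError("feature matrix has no continuous target")
        target = fm.target.to_numpy(dtype=float)

    plan, fingerprint = _fold_plan(
        target if metric == "auc" else np.zeros(len(X), dtype=int),
        stratify=(metric == "auc"), repeats=repeats, folds=folds, seed=seed)

    values = np.full((repeats, folds), np.nan)
    n_skipped = 0
    est = make_estimator(spec, seed=seed)
    for r, splits in enumerate(plan):
        for k, (train_idx, test_idx) in enumerate(splits):
            y_test = target[test_idx]
            fitted = clone(est)
            fitted.fit(X[train_idx], target[train_idx])
            if metric == "auc":
                if len(np.unique(y_test)) < 2:
                    n_skipped += 1
                    continue
                scores = _decision_scores(fitted, X[test_idx])
                values[r, k] = auc(scores, y_test)
            else:
                pred = fitted.predict(X[test_idx])
                if np.ptp(pred) == 0 or np.ptp(y_test) == 0:
                    n_skipped += 1
                    continue
                values[r, k] = spearman(pred, y_test)
    return PairedCVResult(model=spec.family, metric=metric, values=values,
                          fingerprint=fingerprint, seed=seed, n_skipped=n_skipped)


def fit_predict_proba(spec: ModelSpec, train: FeatureMatrix,
                      test: FeatureMatrix, seed: int = 0) -> np.ndarray:
    """Fit on ``train`` and return positive-class probabilities on ``test``.

    Margin-based families are passed through Platt-style sigmoid
    calibration fit on the training data, so every family returns values
    in [0, 1].
    """
    if train.feature_names != test.feature_names:
        diff = sorted(set(train.feature_names) ^ set(test.feature_names))
        raise ValueError(f"train/test feature mismatch: {diff}")
    if train.y is None:
        raise ValueError("training matrix has no binary label")
    est = make_estimator(spec, seed=seed, proba=True)
    est.fit(train.X.to_numpy(dtype=float), train.y.to_numpy())
    model = est[-1]
    X_test = test.X.to_numpy(dtype=float)
    if hasattr(model, "predict_proba"):
        return est.predict_proba(X_test)[:, 1]
    # uncalibrated margin family: squash the decision function
    z = est.decision_function(X_test)
    return 1.0 / (1.0 + np.exp(-z))


def regress_sofa(
    fm: FeatureMatrix,
    spec: ModelSpec,
    repeats: int = 50,
    seed: int = 0,
    folds: int = 10,
    excluded: Sequence[str] = DEFAULT_SOFA_EXCLUSIONS,
) -> PairedCVResult:
    """Repeated-CV Spearman for predicting log-SOFA.

    Features that enter the SOFA criteria (or proxy its organ systems) are
    dropped before fitting; with the default 31-feature matrix this leaves
    23 candidates.  The per-fold Spearman correlates held-out predictions
    with the actual target, and the result's (mean, sd) summarizes all
    repeats x folds values.
    """
    if not spec.is_regressor:
        raise ValueError(f"{spec.family!r} is not a regression family")
    if fm.target is None:
        raise ValueError("feature matrix has no continuous target")
    keep = [f for f in fm.feature_names if f not in set(excluded)]
    if len(keep) < 23:
        import warnings
        warnings.warn(
            f"only {len(keep)} candidate features remain after SOFA-criterion "
            "exclusion; proceeding with the remainder", stacklevel=2)
    return repeated_cv(fm.subset(keep), spec, metric="spearman",
                       repeats=repeats, folds=folds, seed=seed)
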