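"""Feature selection: LASSO support extraction and greedy prefix search.

Two procedures, matched to the model family they serve:

* For logistic regression and naive Bayes: L1-penalized logistic
  regression with the penalty chosen by inner 5-fold cross-validated
  deviance; the features with nonzero coefficients are kept.
* For linear SVM, random forest and adaboost: features are first ranked
  (|weight| of the linear SVM on standardized features, or out-of-fold
  permutation mean decrease in accuracy for the tree ensembles), then the
  cross-validated AUC of every ranking prefix {top-1, ..., all} is
  evaluated and the globally best prefix kept, with ties broken toward
  the smaller prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .matrix import FeatureMatrix
from .modeling import ModelSpec, make_estimator, repeated_cv

RANKING_FAMILIES = ("linear_svm", "random_forest", "adaboost")


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by importance under one model family."""

    features: tuple[str, ...]
    scores: tuple[float, ...]
    family: str

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores must align")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("ranking scores must be non-increasing")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a selection procedure.

    ``trace`` is the CV-AUC per ranking prefix size for the greedy method
    (empty for LASSO, whose support is not prefix-structured).
    """

    selected: tuple[str, ...]
    method: str
    trace: tuple[float, ...] = ()
    chosen_size: int = 0


def choose_prefix(trace: Sequence[float]) -> int:
    """Prefix size with globally maximal AUC; ties favour the smaller prefix."""
    arr = np.asarray(trace, dtype=float)
    if arr.size == 0:
        raise ValueError("empty trace")
    return int(np.argmax(arr)) + 1


def lasso_select(fm: FeatureMatrix, seed: int = 0,
                 n_penalties: int = 15, inner_folds: int = 5) -> SelectionResult:
    """L1-logistic support selection at the minimum-CV-deviance penalty."""
    if fm.y is None:
        raise ValueError("feature matrix has no binary label")
    X = StandardScaler().fit_transform(fm.X.to_numpy(dtype=float))
    y = fm.y.to_numpy()
    Cs = np.logspace(-2.5, 1.5, n_penalties)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    deviance = np.zeros(Cs.size)
    for j, C in enumerate(Cs):
        losses = []
        for train, test in splits:
            clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                     random_state=seed, max_iter=2000)
            clf.fit(X[train], y[train])
            losses.append(log_loss(y[test], clf.predict_proba(X[test])[:, 1],
                                   labels=[0, 1]))
        deviance[j] = np.mean(losses)
    C_best = Cs[int(np.argmin(deviance))]
    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C_best,
                             random_state=seed, max_iter=2000)
    clf.fit(X, y)
    mask = np.abs(clf.coef_.ravel()) > 1e-10
    selected = tuple(np.array(fm.feature_names)[mask])
    if not selected:
        warnings.warn("LASSO selected no features; downstream should fall "
                      "back to the full feature set", stacklevel=2)
    return SelectionResult(selected=selected, method="lasso",
                           chosen_size=len(selected))


def _permutation_importance(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                            seed: int, folds: int = 5,
                            n_permutations: int = 5) -> np.ndarray:
    """Out-of-fold permutation mean decrease in predictive accuracy."""
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    drops = np.zeros(X.shape[1])
    for train, test in cv.split(X, y):
        est = make_estimator(spec, seed=seed)
        est.fit(X[train], y[train])
        base = np.mean(est.predict(X[test]) == y[test])
        for j in range(X.shape[1]):
            for _ in range(n_permutations):
                Xp = X[test].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops[j] += (base - np.mean(est.predict(Xp) == y[test]))
    return drops / (folds * n_permutations)


def rank_features(spec: ModelSpec, fm: FeatureMatrix, seed: int = 0) -> FeatureRanking:
    """Rank features by the family's importance metric (descending).

    Linear SVM ranks by |weight| on standardized features; random forest
    and adaboost by out-of-fold permutation mean decrease in accuracy.
    Deterministic for a fixed seed.
    """
    if spec.family not in RANKING_FAMILIES:
        raise ValueError(
            f"ranking is defined for {RANKING_FAMILIES}, not {spec.family!r}")
    if fm.y is None:
        raise ValueError("feature matrix has no binary label")
    X = fm.X.to_numpy(dtype=float)
    y = fm.y.to_numpy()
    if spec.family == "linear_svm":
        Xs = StandardScaler().fit_transform(X)
        svc = LinearSVC(dual="auto", max_iter=5000, random_state=seed,
                        **spec.params)
        svc.fit(Xs, y)
        importance = np.abs(svc.coef_.ravel())
    else:
        importance = _permutation_importance(spec, X, y, seed=seed)
    order = np.argsort(-importance, kind="stable")
    names = np.array(fm.feature_names)
    return FeatureRanking(features=tuple(names[order]),
                          scores=tuple(importance[order]),
                          family=spec.family)


def greedy_prefix_select(
    ranking: FeatureRanking,
    fm: FeatureMatrix,
    spec: ModelSpec,
    seed: int = 0,
    cv_repeats: int = 1,
    folds: int = 10,
) -> SelectionResult:
    """Evaluate every ranking prefix by CV AUC and keep the best one.

    Features are added in ranking order one at a time; the full AUC trace
    over prefix sizes is retained so the stopping rule can be audited, and
    the returned prefix is the global argmax (smaller prefix on ties).
    """
    unknown = set(ranking.features) - set(fm.feature_names)
    if unknown:
        raise KeyError(f"ranking references unknown features {sorted(unknown)}")
    trace = []
    for k in range(1, len(ranking.features) + 1):
        sub = fm.subset(list(ranking.features[:k]))
        res = repeated_cv(sub, spec, metric="auc", repeats=cv_repeats,
                          folds=folds, seed=seed)
        trace.append(res.mean)
    size = choose_prefix(trace)
    return SelectionResult(selected=tuple(ranking.features[:size]),
                           method="greedy", trace=tuple(trace),
                           chosen_size=size)
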