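"""Per-category decomposition of classifier predictions.

The 11 adjudication categories are reported in eight groups — {1, 9-11}
pooled (never septic / fully recovered) and 2, 3, 4, 5, 6, 7, 8 singly.
Positive-phase groups (2-5) report sensitivity at the probability cutoff;
negative groups report specificity.  The heatmap table ranks patients by
predicted probability and assigns each a confusion-matrix quadrant, and
the per-category coefficient profile fits a one-vs-rest linear margin
classifier per group to show which features drive each phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .matrix import FeatureMatrix
from .modeling import POSITIVE_CATEGORIES

#: Reporting groups: the pooled baseline group then each phase category.
CATEGORY_GROUPS: tuple[tuple[int, ...], ...] = (
    (1, 9, 10, 11), (2,), (3,), (4,), (5,), (6,), (7,), (8,),
)


def _group_name(group: tuple[int, ...]) -> str:
    return "1, 9-11" if len(group) > 1 else str(group[0])


def category_metrics(
    probabilities: Sequence[float],
    categories: Sequence[int],
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Sensitivity/specificity and probability summary per category group.

    A probability exactly at the cutoff counts as predicted positive.
    Positive groups (2-5) report sensitivity = fraction >= cutoff;
    negative groups report specificity = fraction < cutoff.  Empty groups
    report NaN (undefined), never 0.
    """
    p = np.asarray(probabilities, dtype=float)
    c = np.asarray(categories)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rows = []
    for group in CATEGORY_GROUPS:
        mask = np.isin(c, group)
        n = int(mask.sum())
        positive_group = group[0] in POSITIVE_CATEGORIES
        if n == 0:
            metric = np.nan
            mu = sd = np.nan
        else:
            predicted_pos = p[mask] >= cutoff
            metric = float(np.mean(predicted_pos) if positive_group
                           else np.mean(~predicted_pos))
            mu, sd = float(p[mask].mean()), float(p[mask].std(ddof=0))
        rows.append({
            "group": _group_name(group),
            "metric": "sensitivity" if positive_group else "specificity",
            "value": metric, "probability_mean": mu, "probability_sd": sd,
            "n": n,
        })
    return pd.DataFrame(rows)


def heatmap_table(
    probabilities: Sequence[float],
    categories: Sequence[int],
    cutoff: float = 0.5,
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Patients ranked by predicted probability with confusion quadrants.

    Rank 1 is the highest probability (ties broken by stable input order).
    Quadrants combine the true phase side (categories 2-5 positive) with
    the cutoff side (probability >= cutoff predicted positive): TP, FP,
    TN, FN.
    """
    p = np.asarray(probabilities, dtype=float)
    c = np.asarray(categories)
    if patient_ids is None:
        patient_ids = [f"P{i + 1:04d}" for i in range(p.size)]
    order = np.argsort(-p, kind="stable")
    ranks = np.empty(p.size, dtype=int)
    ranks[order] = np.arange(1, p.size + 1)
    truly_pos = np.isin(c, list(POSITIVE_CATEGORIES))
    predicted_pos = p >= cutoff
    quadrant = np.where(
        predicted_pos, np.where(truly_pos, "TP", "FP"),
        np.where(truly_pos, "FN", "TN"))
    return pd.DataFrame({
        "patient": list(patient_ids), "category": c,
        "probability": p, "rank": ranks, "quadrant": quadrant,
    })


def per_category_coefficients(
    fm: FeatureMatrix,
    min_group_size: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """One-vs-rest linear-SVM weight profile per category group.

    For each group with at least ``min_group_size`` members, fits a linear
    margin classifier of group-vs-rest on standardized features and
    returns its unit-norm weight vector; groups too small for a fit appear
    as all-NaN rows.
    """
    if fm.categories is None:
        raise ValueError("feature matrix has no categories")
    X = StandardScaler().fit_transform(fm.X.to_numpy(dtype=float))
    cats = fm.categories.to_numpy()
    rows = {}
    for group in CATEGORY_GROUPS:
        mask = np.isin(cats, group).astype(int)
        name = _group_name(group)
        if mask.sum() < min_group_size or mask.sum() == len(mask):
            rows[name] = np.full(X.shape[1], np.nan)
            continue
        svc = LinearSVC(dual="auto", max_iter=5000, random_state=seed)
        svc.fit(X, mask)
        w = svc.coef_.ravel()
        norm = np.linalg.norm(w)
        rows[name] = w / norm if norm > 0 else w
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=fm.feature_names)
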