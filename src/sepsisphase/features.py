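"""Assembly of the model-ready feature matrix from a cohort.

Combines the two feature blocks the analysis compares:

* ``biomarkers`` — the 15-marker panel after censored-lognormal
  conditional-expectation imputation and quantile normalization;
* ``emr`` — one threshold-excursion score per charted vital/lab parameter
  within the configured window (16 by default).

Also attaches the binary early-to-peak label, the raw category, and the
log-SOFA regression target computed from each patient's draw-time snapshot.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .matrix import FeatureMatrix
from .modeling import binarize_labels
from .severity import sofa_score
from .synthetic import Cohort
from .vitals import WindowSpec, featurize_vitals


def fit_marker_distributions(cohort: Cohort) -> dict[str, bm.CensoredFit]:
    """Censored-lognormal fits for every marker with censored readings.

    Markers whose readings are all observed need no fit (imputation will
    not touch them); markers with too few observed values to fit are left
    out, which downstream imputation treats as impute-at-limit.
    """
    by_marker: dict[str, list[bm.BiomarkerMeasurement]] = {}
    for rec in cohort.records:
        for m in rec.markers:
            by_marker.setdefault(m.marker, []).append(m)
    fits: dict[str, bm.CensoredFit] = {}
    for name, values in by_marker.items():
        if all(v.censor == bm.OBSERVED for v in values):
            continue
        try:
            fits[name] = bm.fit_censored_lognormal(values)
        except ValueError:
            continue  # fallback: censored readings stay at the limit
    return fits


def biomarker_features(
    cohort: Cohort,
    impute: bool = True,
    quantile: bool = True,
    fits: Mapping[str, bm.CensoredFit] | None = None,
) -> pd.DataFrame:
    """Patients x markers table of processed concentrations."""
    if fits is None:
        fits = fit_marker_distributions(cohort) if impute else {}
    index = pd.Index([r.patient_id for r in cohort.records], name="patient")
    columns: dict[str, np.ndarray] = {}
    marker_names = [m.marker for m in cohort.records[0].markers]
    panels = []
    for rec in cohort.records:
        panel = rec.markers
        if impute:
            panel = [
                m if (m.censor == bm.OBSERVED or m.marker not in fits)
                else bm.impute_censored([m], fits)[0]
                for m in panel
            ]
        panels.append({m.marker: m.concentration for m in panel})
    for name in marker_names:
        col = np.array([p[name] for p in panels], dtype=float)
        if quantile:
            col = bm.quantile_normalize(col)
        columns[name] = col
    return pd.DataFrame(columns, index=index)


def build_feature_matrix(
    cohort: Cohort,
    window: WindowSpec | None = None,
    parameters: Sequence[str] | None = None,
    impute: bool = True,
    quantile: bool = True,
) -> FeatureMatrix:
    """Full feature matrix: biomarker block + EMR block + labels/targets."""
    window = window or WindowSpec()
    bio = biomarker_features(cohort, impute=impute, quantile=quantile)
    emr = featurize_vitals(cohort, window, parameters=parameters)
    X = pd.concat([bio, emr], axis=1)

    index = bio.index
    cats = pd.Series(cohort.categories, index=index, name="category")
    y = pd.Series(binarize_labels(cats), index=index, name="label")
    sofa = pd.Series(
        [sofa_score(rec.snapshot).total for rec in cohort.records],
        index=index, name="sofa", dtype=float)
    target = np.log(sofa + 1.0)
    target.name = "log_sofa"

    emr_scores = [c for c in emr.columns if not c.endswith("__missing")]
    return FeatureMatrix(
        X=X, y=y, categories=cats, target=target,
        blocks={"biomarkers": list(bio.columns), "emr": list(emr.columns),
                "emr_scores": emr_scores},
    )
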