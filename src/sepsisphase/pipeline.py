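"""End-to-end pipeline runs: simulate, featurize, train, select, compare,
stratify, with provenance and structured logging.

The run configuration is a YAML/JSON document with a ``simulate`` block (or
``inputs`` pointing at existing tables), a window, the model list, repeat
count and seed.  Every output CSV is accompanied by a JSON provenance
record (config hash, seed, package versions), and a rerun with the same
configuration is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from . import __version__, io
from .comparison import auc_vs_window, paired_auc_comparison
from .features import build_feature_matrix
from .matrix import FeatureMatrix
from .modeling import ModelSpec, fit_predict_proba, regress_sofa, repeated_cv
from .selection import greedy_prefix_select, lasso_select, rank_features
from .severity import qsofa_score, sirs_count, sofa_score
from .stratification import (
    category_metrics, heatmap_table, per_category_coefficients,
)
from .synthetic import MarkerSpec, SimulationConfig, VitalSpec, generate_cohort
from .vitals import WindowSpec

log = logging.getLogger("sepsisphase")

DEFAULT_MODELS = ("logistic_regression", "linear_svm", "random_forest",
                  "adaboost", "naive_bayes")
DEFAULT_FEATURE_SETS = ("all", "emr_scores", "biomarkers")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out: str = "run_output"
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides
    inputs: str | None = None                      # directory of existing tables
    hours_before: float = 48.0
    hours_after: float = 1.0
    models: Sequence[str] = DEFAULT_MODELS
    feature_sets: Sequence[str] = DEFAULT_FEATURE_SETS
    repeats: int = 1000
    selection: bool = True
    selection_model: str = "linear_svm"
    cutoff: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        block = dict(self.simulate)
        if "markers" in block:
            block["markers"] = [MarkerSpec(**m) for m in block["markers"]]
        if "vitals" in block:
            block["vitals"] = [
                VitalSpec(**{**v, "normal_range": tuple(v["normal_range"])})
                for v in block["vitals"]
            ]
        if "severity_means" in block:
            block["severity_means"] = {int(k): float(v)
                                       for k, v in block["severity_means"].items()}
        block.setdefault("seed", self.seed)
        return SimulationConfig(**block)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cross_val_probabilities(fm: FeatureMatrix, spec: ModelSpec,
                            folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold predicted probabilities from one seeded stratified split."""
    if fm.y is None:
        raise ValueError("feature matrix has no binary label")
    y = fm.y.to_numpy()
    probs = np.full(len(y), np.nan)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in cv.split(np.zeros((len(y), 1)), y):
        train = FeatureMatrix(X=fm.X.iloc[train_idx], y=fm.y.iloc[train_idx],
                              categories=None, target=None)
        test = FeatureMatrix(X=fm.X.iloc[test_idx], y=fm.y.iloc[test_idx],
                             categories=None, target=None)
        probs[test_idx] = fit_predict_proba(spec, train, test, seed=seed)
    return probs


def severity_table(cohort) -> pd.DataFrame:
    """Per-patient SIRS / qSOFA / SOFA scores from the draw-time snapshot."""
    rows = []
    for rec in cohort.records:
        sofa = sofa_score(rec.snapshot)
        rows.append({
            "patient": rec.patient_id, "category": rec.category,
            "sirs": sirs_count(rec.snapshot),
            "qsofa": qsofa_score(rec.snapshot),
            "sofa": sofa.total, "sofa_completeness": sofa.completeness,
            **{f"sofa_{k}": v for k, v in sofa.subscores.items()},
        })
    return pd.DataFrame(rows)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.1fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.1fs (%s)", name, dt, exc)
            return False
    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end-to-end; returns the run report."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seed": config.seed,
                    "version": __version__}

    with _stage("cohort"):
        if config.inputs:
            cohort = io.read_cohort(config.inputs)
        else:
            cohort = generate_cohort(config.simulation_config())
            io.write_cohort(cohort, out / "cohort")
        report["n_patients"] = len(cohort)

    with _stage("featurize"):
        window = WindowSpec(config.hours_before, config.hours_after)
        fm = build_feature_matrix(cohort, window)
        io.write_features(fm, out / "features.csv", provenance={
            "window_hours_before": config.hours_before,
            "window_hours_after": config.hours_after,
            "normalization": "censored-lognormal conditional-expectation "
                             "imputation, then quantile ranks",
            "abnormality_score_normalizer": "full window duration T",
            "config_digest": config.digest(),
        })
        report["n_features"] = len(fm.feature_names)

    with _stage("severity"):
        severity_table(cohort).to_csv(out / "severity_scores.csv", index=False)

    results: dict[tuple[str, str], object] = {}
    summary_rows = []
    with _stage("train"):
        for family in config.models:
            spec = ModelSpec(family)
            for fs in config.feature_sets:
                res = repeated_cv(fm.block(fs), spec, metric="auc",
                                  repeats=config.repeats, seed=config.seed)
                results[(family, fs)] = res
                summary_rows.append({
                    "model": family, "feature_set": fs,
                    "mean_auc": res.mean, "sd_auc": res.sd,
                    "repeats": config.repeats, "skipped_folds": res.n_skipped,
                })
        pd.concat([r.long_frame() for r in results.values()]
                  ).to_csv(out / "cv_folds.csv", index=False)
        pd.DataFrame(summary_rows).to_csv(out / "cv_summary.csv", index=False)
        report["cv_summary"] = summary_rows

    if config.selection:
        with _stage("select"):
            spec = ModelSpec(config.selection_model)
            if config.selection_model in ("logistic_regression", "naive_bayes"):
                sel = lasso_select(fm, seed=config.seed)
                ranking = None
            else:
                ranking = rank_features(spec, fm, seed=config.seed)
                sel = greedy_prefix_select(ranking, fm, spec, seed=config.seed)
                pd.DataFrame({
                    "feature": ranking.features, "score": ranking.scores,
                    "rank": np.arange(1, len(ranking.features) + 1),
                }).to_csv(out / "ranking.csv", index=False)
            (out / "selection.json").write_text(json.dumps({
                "method": sel.method, "selected": list(sel.selected),
                "auc_trace": list(sel.trace), "chosen_size": sel.chosen_size,
            }, indent=1))
            report["selected_features"] = list(sel.selected)
            if sel.selected:
                res = repeated_cv(fm.subset(list(sel.selected)), spec,
                                  repeats=config.repeats, seed=config.seed)
                report["selected_mean_auc"] = res.mean

    with _stage("compare"):
        comp_rows = []
        base_model = (config.selection_model
                      if config.selection_model in config.models
                      else config.models[0])
        for fs in config.feature_sets:
            if fs == "all":
                continue
            summary = paired_auc_comparison(results[(base_model, "all")],
                                            results[(base_model, fs)])
            comp_rows.append({
                "model": base_model, "a": "all", "b": fs,
                "n_pairs": summary.n_pairs,
                "proportion_above_zero": summary.proportion_above_zero,
                "proportion_ties": summary.proportion_ties,
                "mean_difference": summary.mean_difference,
                "q2.5": summary.quantiles[0], "median": summary.quantiles[1],
                "q97.5": summary.quantiles[2],
            })
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
        report["comparisons"] = comp_rows

    with _stage("sofa_regression"):
        reg = regress_sofa(fm, ModelSpec("linear_regression"),
                           repeats=min(config.repeats, 50), seed=config.seed)
        report["sofa_spearman_mean"] = reg.mean
        report["sofa_spearman_sd"] = reg.sd

    with _stage("stratify"):
        spec = ModelSpec(config.selection_model)
        probs = cross_val_probabilities(fm, spec, seed=config.seed)
        category_metrics(probs, fm.categories.to_numpy(), config.cutoff
                         ).to_csv(out / "category_metrics.csv", index=False)
        heatmap_table(probs, fm.categories.to_numpy(), config.cutoff,
                      patient_ids=list(fm.X.index)
                      ).to_csv(out / "heatmap.csv", index=False)
        per_category_coefficients(fm).to_csv(out / "category_coefficients.csv")

    provenance = {
        "config": dataclasses.asdict(config), "digest": config.digest(),
        "versions": {"sepsisphase": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, default=str, indent=1))
    (out / "report.json").write_text(json.dumps(report, default=str, indent=1))
    return report
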