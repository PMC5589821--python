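"""Reading and writing the pipeline's long-format CSV tables.

A cohort is exchanged as three tables plus a ground-truth sidecar:

* ``observations.csv`` — patient, time_min, parameter, value (vital/lab
  series, timestamps in minutes relative to the blood draw);
* ``biomarkers.csv`` — patient, marker, concentration, censor, batch;
* ``patients.csv`` — patient, category, draw_time_min, demographics and
  the draw-time SOFA-component snapshot;
* ``truth.json`` — the simulation parameters that produced a synthetic
  cohort (absent for real data).

Engineered features travel as one wide ``features.csv`` with ``label``,
``category`` and ``log_sofa`` columns alongside the feature columns, plus
a JSON provenance header file naming the blocks and window.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerMeasurement
from .matrix import FeatureMatrix
from .severity import ClinicalSnapshot
from .synthetic import Cohort, PatientRecord, SimulationConfig
from .vitals import NORMAL_RANGES, VitalSeries

SNAPSHOT_FIELDS = [f.name for f in dataclasses.fields(ClinicalSnapshot)]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the three long-format tables plus the truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    obs_rows, bio_rows, meta_rows = [], [], []
    for rec in cohort.records:
        for name, series in rec.vitals.items():
            for t, v in zip(series.times, series.values):
                obs_rows.append((rec.patient_id, t, name, v))
        for m in rec.markers:
            bio_rows.append((rec.patient_id, m.marker, m.concentration,
                             m.censor, m.batch))
        meta = {"patient": rec.patient_id, "category": rec.category,
                "draw_time_min": rec.draw_time, "age": rec.age, "sex": rec.sex}
        for f in SNAPSHOT_FIELDS:
            meta[f] = getattr(rec.snapshot, f)
        meta_rows.append(meta)

    paths = {
        "observations": outdir / "observations.csv",
        "biomarkers": outdir / "biomarkers.csv",
        "patients": outdir / "patients.csv",
        "truth": outdir / "truth.json",
    }
    pd.DataFrame(obs_rows, columns=["patient", "time_min", "parameter", "value"]
                 ).to_csv(paths["observations"], index=False)
    pd.DataFrame(bio_rows, columns=["patient", "marker", "concentration",
                                    "censor", "batch"]
                 ).to_csv(paths["biomarkers"], index=False)
    pd.DataFrame(meta_rows).to_csv(paths["patients"], index=False)

    truth = {
        "config": dataclasses.asdict(cohort.truth),
        "severity": {r.patient_id: r.severity for r in cohort.records},
    }
    paths["truth"].write_text(json.dumps(truth, default=_json_default, indent=1))
    return paths


def read_cohort(directory: str | Path,
                normal_ranges: Mapping[str, tuple[float, float]] | None = None,
                ) -> Cohort:
    """Reconstruct a cohort from the three tables (truth sidecar optional)."""
    directory = Path(directory)
    obs = pd.read_csv(directory / "observations.csv")
    bio = pd.read_csv(directory / "biomarkers.csv")
    meta = pd.read_csv(directory / "patients.csv")

    ranges = dict(NORMAL_RANGES)
    severity: dict[str, float] = {}
    config = SimulationConfig()
    truth_path = directory / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        severity = truth.get("severity", {})
        for v in truth.get("config", {}).get("vitals", []):
            ranges[v["name"]] = tuple(v["normal_range"])
    if normal_ranges:
        ranges.update(normal_ranges)

    obs_by_patient = dict(tuple(obs.groupby("patient", sort=False)))
    bio_by_patient = dict(tuple(bio.groupby("patient", sort=False)))

    records = []
    for row in meta.itertuples(index=False):
        pid = row.patient
        vitals: dict[str, VitalSeries] = {}
        if pid in obs_by_patient:
            for name, g in obs_by_patient[pid].groupby("parameter", sort=False):
                g = g.sort_values("time_min")
                vitals[name] = VitalSeries(
                    parameter=name,
                    times=g["time_min"].to_numpy(dtype=float),
                    values=g["value"].to_numpy(dtype=float),
                    normal_range=ranges.get(name, (-np.inf, np.inf)),
                )
        markers = []
        if pid in bio_by_patient:
            for m in bio_by_patient[pid].itertuples(index=False):
                markers.append(BiomarkerMeasurement(
                    marker=m.marker, concentration=float(m.concentration),
                    censor=m.censor, batch=int(m.batch)))
        snap_kwargs = {}
        for f in SNAPSHOT_FIELDS:
            v = getattr(row, f, None)
            snap_kwargs[f] = None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        records.append(PatientRecord(
            patient_id=pid, category=int(row.category),
            severity=float(severity.get(pid, np.nan)),
            draw_time=float(row.draw_time_min), markers=markers,
            vitals=vitals, snapshot=ClinicalSnapshot(**snap_kwargs),
            age=float(row.age), sex=str(row.sex)))
    return Cohort(records=records, truth=config)


def write_features(fm: FeatureMatrix, path: str | Path,
                   provenance: dict | None = None) -> Path:
    """Write the wide feature table plus a JSON provenance header file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = fm.X.copy()
    if fm.y is not None:
        df["label"] = fm.y
    if fm.categories is not None:
        df["category"] = fm.categories
    if fm.target is not None:
        df["log_sofa"] = fm.target
    df.to_csv(path, index=True)
    meta = {"blocks": fm.blocks, "features": fm.feature_names}
    if provenance:
        meta.update(provenance)
    path.with_suffix(".json").write_text(
        json.dumps(meta, default=_json_default, indent=1))
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    """Read a feature table written by :func:`write_features`."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(".json")
    blocks: dict[str, list[str]] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        blocks = {k: list(v) for k, v in meta.get("blocks", {}).items()}
    special = [c for c in ("label", "category", "log_sofa") if c in df.columns]
    X = df.drop(columns=special)
    return FeatureMatrix(
        X=X,
        y=df["label"].astype(int) if "label" in special else None,
        categories=df["category"].astype(int) if "category" in special else None,
        target=df["log_sofa"] if "log_sofa" in special else None,
        blocks=blocks,
    )
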