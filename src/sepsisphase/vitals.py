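"""Threshold-excursion scoring of irregular vital-sign / lab time series.

Each charted parameter (pulse, temperature, white-cell count, ...) is
collapsed into a single dimensionless score per patient: the time-normalized
integral of the percent deviation beyond the parameter's clinical normal
range, evaluated over a window anchored at the biomarker blood-draw time.
The series is treated as a left-constant step function between charting
times, so the integral is an exact Riemann sum over the charted segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import Cohort

INF = math.inf

#: Default clinical normal ranges, keyed by parameter name.  The first five
#: follow the SIRS / common bedside limits; the rest are ordinary reference
#: intervals for labs charted on most inpatients.  One-sided ranges use
#: +/-inf for the unbounded side.  All are overridable per series.
NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "pulse": (-INF, 90.0),               # bpm
    "temperature": (36.0, 38.0),         # deg C
    "respirations": (-INF, 20.0),        # breaths/min
    "systolic_bp": (90.0, INF),          # mmHg
    "wbc": (4.0, 12.0),                  # 10^3 cells/uL
    "lactic_acid": (-INF, 2.0),          # mmol/L
    "pco2": (35.0, 45.0),                # mmHg
    "oxygen_saturation": (92.0, INF),    # %
    "diastolic_bp": (60.0, INF),         # mmHg
    "mean_arterial_pressure": (65.0, INF),  # mmHg
    "glucose": (70.0, 180.0),            # mg/dL
    "creatinine": (-INF, 1.2),           # mg/dL
    "platelets": (150.0, INF),           # 10^3/uL
    "bilirubin": (-INF, 1.2),            # mg/dL
    "bun": (-INF, 20.0),                 # mg/dL
    "hemoglobin": (12.0, INF),           # g/dL
}

#: The post-draw window grid explored by the window-curve analysis (hours).
POST_SAMPLE_HOURS: tuple[int, ...] = (0, 1, 4, 8, 12, 16, 20, 24)


@dataclass(frozen=True)
class VitalSeries:
    """One parameter's timestamped values for one patient.

    Timestamps are minutes relative to a common epoch (the cohort uses the
    blood-draw time as minute 0).  Timestamps must be strictly increasing
    and values finite.
    """

    parameter: str
    times: np.ndarray
    values: np.ndarray
    normal_range: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError(f"timestamps of {self.parameter!r} must be strictly increasing")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in series {self.parameter!r}")
        lo, hi = self.normal_range
        if not lo < hi:
            raise ValueError(f"normal range for {self.parameter!r} must satisfy L < U, got {self.normal_range}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class WindowSpec:
    """Observation window anchored at the biomarker draw time.

    ``hours_after`` conventionally comes from :data:`POST_SAMPLE_HOURS`
    (the grid used by the window-curve analysis) but any non-negative value
    is accepted.  ``anchor`` is the draw time in the series' minute scale.
    """

    hours_before: float = 48.0
    hours_after: float = 1.0
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.anchor) and math.isfinite(self.hours_before)
                and math.isfinite(self.hours_after)):
            raise ValueError("window anchor and extents must be finite")
        if self.hours_before < 0 or self.hours_after < 0:
            raise ValueError("window extents must be non-negative")

    @property
    def start(self) -> float:
        return self.anchor - 60.0 * self.hours_before

    @property
    def end(self) -> float:
        return self.anchor + 60.0 * self.hours_after

    @property
    def duration_minutes(self) -> float:
        return 60.0 * (self.hours_before + self.hours_after)


def window_clip(series: VitalSeries, spec: WindowSpec) -> VitalSeries:
    """Restrict a series to the closed window [start, end].

    Both boundaries are inclusive, so an observation charted exactly at
    ``anchor - hours_before`` is retained.  The result may be empty.
    """
    mask = (series.times >= spec.start) & (series.times <= spec.end)
    return replace(series, times=series.times[mask], values=series.values[mask])


def _percent_excursion(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Percent deviation beyond the violated bound; 0 inside [lo, hi]."""
    p = np.zeros_like(values, dtype=float)
    if math.isfinite(lo):
        below = values < lo
        p[below] = (lo - values[below]) / lo
    if math.isfinite(hi):
        above = values > hi
        p[above] = (values[above] - hi) / hi
    return p


def abnormality_score(series: VitalSeries, spec: WindowSpec) -> float:
    """Time-normalized integral of percent threshold excursion.

    The series is interpolated as a left-constant step function: each value
    holds from its own timestamp to the next one (the last value holds to
    the window end; nothing is extrapolated before the first observation).
    On every sub-interval where the held value v lies outside [L, U] the
    integrand is (L - v)/L below the range or (v - U)/U above it, and the
    integral is divided by the *full* window duration T, so a parameter
    that is never abnormal scores 0 and a parameter pinned at a constant
    excursion scores that excursion's percent deviation.

    Raises ``ValueError`` if the window has non-positive duration.
    """
    T = spec.duration_minutes
    if T <= 0:
        raise ValueError("window duration must be positive")
    clipped = window_clip(series, spec)
    if len(clipped) == 0:
        return 0.0
    lo, hi = clipped.normal_range
    # segment boundaries: each observation holds until the next, last one
    # holds to the window end
    edges = np.append(clipped.times, spec.end)
    dt = np.diff(edges)
    p = _percent_excursion(clipped.values, lo, hi)
    return float(np.sum(dt * p) / T)


def featurize_vitals(
    cohort: "Cohort",
    spec: WindowSpec,
    parameters: Sequence[str] | None = None,
    normal_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Build the EMR feature block: one excursion score column per parameter.

    A patient with no observations of a parameter scores 0 ("no documented
    abnormality") and, if any patient in the cohort is missing that
    parameter, a companion ``<name>__missing`` indicator column records the
    fact.  Indicator columns are appended after the score columns and are
    not counted among the configured parameters.
    """
    ranges = dict(NORMAL_RANGES)
    if normal_ranges:
        ranges.update(normal_ranges)
    if parameters is None:
        parameters = list(NORMAL_RANGES)
    unknown = [p for p in parameters if p not in ranges]
    if unknown:
        raise KeyError(
            f"unknown vital parameter(s) {unknown}; configured parameters are "
            f"{sorted(ranges)}"
        )

    rows: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    n = len(cohort.records)
    for name in parameters:
        scores = np.zeros(n)
        absent = np.zeros(n)
        for i, rec in enumerate(cohort.records):
            series = rec.vitals.get(name)
            if series is None or len(series) == 0:
                absent[i] = 1.0
                continue
            w = replace(spec, anchor=rec.draw_time)
            scores[i] = abnormality_score(series, w)
        rows[name] = scores
        if absent.any():
            missing[f"{name}__missing"] = absent
    index = pd.Index([rec.patient_id for rec in cohort.records], name="patient")
    return pd.DataFrame({**rows, **missing}, index=index)
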