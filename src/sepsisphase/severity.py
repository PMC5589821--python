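"""SIRS, qSOFA and SOFA severity scores from a point-in-time snapshot.

All three scores follow their consensus criterion tables (SIRS from the
classic systemic-inflammatory-response definition; qSOFA and SOFA from the
Sepsis-3 consensus).  Missing components score 0 — the standard clinical
convention — and SOFA additionally reports the fraction of its six organ
systems that could actually be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional


@dataclass(frozen=True)
class ClinicalSnapshot:
    """Point-in-time observations; any field may be None (not measured).

    ``vasopressor_tier`` encodes vasopressor support intensity:
    0 = none, 1 = low-dose (dopamine <= 5 ug/kg/min or dobutamine),
    2 = moderate (dopamine > 5 or nor/epinephrine <= 0.1 ug/kg/min),
    3 = high (dopamine > 15 or nor/epinephrine > 0.1).
    """

    temperature: Optional[float] = None        # deg C
    pulse: Optional[float] = None              # bpm
    respirations: Optional[float] = None       # /min
    wbc: Optional[float] = None                # 10^3/uL
    systolic_bp: Optional[float] = None        # mmHg
    gcs: Optional[float] = None                # Glasgow Coma Scale, 3-15
    pao2_fio2: Optional[float] = None          # mmHg ratio
    platelets: Optional[float] = None          # 10^3/uL
    bilirubin: Optional[float] = None          # mg/dL
    mean_arterial_pressure: Optional[float] = None  # mmHg
    vasopressor_tier: Optional[int] = None     # 0-3, see class docstring
    creatinine: Optional[float] = None         # mg/dL
    urine_output: Optional[float] = None       # mL/day

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SofaResult:
    total: int
    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int
    completeness: float  # fraction of the six organ systems with any data

    @property
    def subscores(self) -> dict[str, int]:
        return {
            "respiration": self.respiration, "coagulation": self.coagulation,
            "liver": self.liver, "cardiovascular": self.cardiovascular,
            "cns": self.cns, "renal": self.renal,
        }


def sirs_count(s: ClinicalSnapshot) -> int:
    """Number of SIRS criteria met (0-4); absent fields count as not met.

    Criteria: temperature > 38 or < 36 degC; pulse > 90 bpm;
    respirations > 20 /min; WBC > 12 or < 4 (x10^3/uL).
    """
    n = 0
    if s.temperature is not None and (s.temperature > 38.0 or s.temperature < 36.0):
        n += 1
    if s.pulse is not None and s.pulse > 90.0:
        n += 1
    if s.respirations is not None and s.respirations > 20.0:
        n += 1
    if s.wbc is not None and (s.wbc > 12.0 or s.wbc < 4.0):
        n += 1
    return n


def qsofa_score(s: ClinicalSnapshot) -> int:
    """qSOFA (0-3): respirations >= 22; systolic BP <= 100 (inclusive); GCS < 15."""
    n = 0
    if s.respirations is not None and s.respirations >= 22.0:
        n += 1
    if s.systolic_bp is not None and s.systolic_bp <= 100.0:
        n += 1
    if s.gcs is not None and s.gcs < 15.0:
        n += 1
    return n


def _respiration(ratio: Optional[float]) -> int:
    # Ratio-only convention: ventilatory-support status is not part of the
    # snapshot, so 3 and 4 are assigned from the ratio alone.
    if ratio is None:
        return 0
    if ratio < 100:
        return 4
    if ratio < 200:
        return 3
    if ratio < 300:
        return 2
    if ratio < 400:
        return 1
    return 0


def _coagulation(platelets: Optional[float]) -> int:
    if platelets is None:
        return 0
    if platelets < 20:
        return 4
    if platelets < 50:
        return 3
    if platelets < 100:
        return 2
    if platelets < 150:
        return 1
    return 0


def _liver(bilirubin: Optional[float]) -> int:
    if bilirubin is None:
        return 0
    if bilirubin >= 12.0:
        return 4
    if bilirubin >= 6.0:
        return 3
    if bilirubin >= 2.0:
        return 2
    if bilirubin >= 1.2:
        return 1
    return 0


def _cardiovascular(map_: Optional[float], tier: Optional[int]) -> int:
    from_tier = 0
    if tier is not None and tier > 0:
        from_tier = min(int(tier) + 1, 4)   # tier 1 -> 2, 2 -> 3, 3 -> 4
    from_map = 1 if (map_ is not None and map_ < 70.0) else 0
    return max(from_tier, from_map)


def _cns(gcs: Optional[float]) -> int:
    if gcs is None:
        return 0
    if gcs < 6:
        return 4
    if gcs <= 9:
        return 3
    if gcs <= 12:
        return 2
    if gcs <= 14:
        return 1
    return 0


def _renal(creatinine: Optional[float], urine: Optional[float]) -> int:
    from_cr = 0
    if creatinine is not None:
        if creatinine >= 5.0:
            from_cr = 4
        elif creatinine >= 3.5:
            from_cr = 3
        elif creatinine >= 2.0:
            from_cr = 2
        elif creatinine >= 1.2:
            from_cr = 1
    from_urine = 0
    if urine is not None:
        if urine < 200:
            from_urine = 4
        elif urine < 500:
            from_urine = 3
    return max(from_cr, from_urine)


def sofa_score(s: ClinicalSnapshot) -> SofaResult:
    """Total SOFA (0-24) with its six organ subscores.

    Absent organ systems score 0; ``completeness`` is the fraction of
    systems with at least one measured input.
    """
    sub = {
        "respiration": _respiration(s.pao2_fio2),
        "coagulation": _coagulation(s.platelets),
        "liver": _liver(s.bilirubin),
        "cardiovascular": _cardiovascular(s.mean_arterial_pressure, s.vasopressor_tier),
        "cns": _cns(s.gcs),
        "renal": _renal(s.creatinine, s.urine_output),
    }
    present = [
        s.pao2_fio2 is not None,
        s.platelets is not None,
        s.bilirubin is not None,
        s.mean_arterial_pressure is not None or s.vasopressor_tier is not None,
        s.gcs is not None,
        s.creatinine is not None or s.urine_output is not None,
    ]
    return SofaResult(total=sum(sub.values()), completeness=sum(present) / 6.0, **sub)
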