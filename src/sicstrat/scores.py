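"""Shock index, estimated creatinine clearance, and the Shock Index-C score.

The shock index (SI) is heart rate over systolic blood pressure; values
near or above 1 indicate haemodynamic compromise. Shock Index-C (SIC)
augments SI with renal function:

    SIC = 100 * SI - CCr

where CCr is the estimated creatinine clearance in mL/min. Higher SIC is
worse (faster heart rate, lower pressure, or worse kidneys all raise it).

Two CCr variants are provided. The default ``as_printed`` form is the
weight-free abbreviation

    CCr = (140 - age) / Scr        (x 0.85 for women)

which matches the cohort-level mean clearance the score was derived with.
``full_cockcroft_gault`` is the standard Cockcroft-Gault estimate

    CCr = (140 - age) * weight / (72 * Scr)   (x 0.85 for women)

and requires body weight; the two coincide exactly at weight = 72 kg.

Stratification follows the score's clinical use: tertile cutpoints at
-30 and -5 (T1: SIC < -30, T2: -30 <= SIC < -5, T3: SIC >= -5) and a
binary high-risk flag at SIC > 10 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .cohort import Cohort, PatientRecord, Sex
from .errors import ValidationError

__all__ = [
    "CcrVariant",
    "Tertile",
    "ScoreResult",
    "ScoredCohort",
    "shock_index",
    "creatinine_clearance",
    "sic_score",
    "sic_tertile",
    "sic_binary",
    "score_cohort",
    "DEFAULT_CUTOFF",
    "DEFAULT_TERTILE_CUTPOINTS",
]

DEFAULT_CUTOFF = 10.0
DEFAULT_TERTILE_CUTPOINTS = (-30.0, -5.0)


class CcrVariant(str, Enum):
    AS_PRINTED = "as_printed"
    FULL_COCKCROFT_GAULT = "full_cockcroft_gault"


class Tertile(str, Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"


def shock_index(heart_rate: float, sbp: float) -> float:
    """Heart rate (bpm) over systolic blood pressure (mmHg)."""
    if sbp <= 0:
        raise ValidationError(f"sbp must be > 0, got {sbp}")
    if heart_rate <= 0:
        raise ValidationError(f"heart_rate must be > 0, got {heart_rate}")
    return heart_rate / sbp


def creatinine_clearance(age: float, sex: Sex, scr: float,
                         weight: float | None = None,
                         variant: CcrVariant | str = CcrVariant.AS_PRINTED,
                         ) -> float:
    """Estimated creatinine clearance in mL/min (Cockcroft-Gault family).

    ``as_printed`` ignores weight and the 72 divisor; the ``full`` variant is
    standard Cockcroft-Gault and requires weight in kg. Women get the 0.85
    factor in both.
    """
    variant = CcrVariant(variant)
    if scr <= 0:
        raise ValidationError(f"scr must be > 0, got {scr}")
    if not 18 <= age < 140:
        raise ValidationError(
            f"age must be in [18, 140) for a positive clearance, got {age}")
    ccr = (140.0 - age) / scr
    if variant is CcrVariant.FULL_COCKCROFT_GAULT:
        if weight is None:
            raise ValidationError(
                "weight is required for the full Cockcroft-Gault variant")
        ccr *= weight / 72.0
    if Sex(sex) is Sex.FEMALE:
        ccr *= 0.85
    return ccr


def sic_tertile(sic: float,
                cutpoints: tuple[float, float] = DEFAULT_TERTILE_CUTPOINTS,
                ) -> Tertile:
    """Assign a SIC value to its risk tertile.

    Boundaries are left-closed on the upper strata: a value exactly at the
    lower cutpoint belongs to T2 and exactly at the upper cutpoint to T3, so
    the three intervals partition the real line.
    """
    if not math.isfinite(sic):
        raise ValidationError(f"SIC must be finite, got {sic}")
    lo, hi = cutpoints
    if not lo < hi:
        raise ValidationError(f"cutpoints must increase, got {cutpoints}")
    if sic < lo:
        return Tertile.T1
    if sic < hi:
        return Tertile.T2
    return Tertile.T3


def sic_binary(sic: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """High-risk flag: strictly above the cutoff (the cutoff value itself is
    low-risk)."""
    if not math.isfinite(sic):
        raise ValidationError(f"SIC must be finite, got {sic}")
    return sic > cutoff


@dataclass(frozen=True)
class ScoreResult:
    """Per-patient score components and strata.

    ``sic == si100 - ccr`` exactly; stratification uses the full-precision
    value (no rounding anywhere).
    """

    si: float
    si100: float
    ccr: float
    sic: float
    tertile: Tertile
    high_risk: bool


def sic_score(record: PatientRecord,
              variant: CcrVariant | str = CcrVariant.AS_PRINTED,
              cutoff: float = DEFAULT_CUTOFF,
              cutpoints: tuple[float, float] = DEFAULT_TERTILE_CUTPOINTS,
              ) -> ScoreResult:
    """Compute SI, CCr, SIC and strata for one patient."""
    si = shock_index(record.heart_rate, record.sbp)
    ccr = creatinine_clearance(record.age, record.sex, record.scr,
                               weight=record.weight, variant=variant)
    sic = si * 100.0 - ccr
    return ScoreResult(si=si, si100=si * 100.0, ccr=ccr, sic=sic,
                       tertile=sic_tertile(sic, cutpoints),
                       high_risk=sic_binary(sic, cutoff))


@dataclass(frozen=True)
class ScoredCohort:
    """A cohort with one :class:`ScoreResult` per record, aligned by order."""

    cohort: Cohort
    scores: tuple[ScoreResult, ...]
    ccr_variant: CcrVariant

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.cohort):
            raise ValidationError("scores must align one-to-one with records")

    def to_frame(self) -> pd.DataFrame:
        """Cohort frame with si, si100, ccr, sic, tertile, high_risk columns
        appended."""
        df = self.cohort.to_frame()
        df["si"] = [s.si for s in self.scores]
        df["si100"] = [s.si100 for s in self.scores]
        df["ccr"] = [s.ccr for s in self.scores]
        df["sic"] = [s.sic for s in self.scores]
        df["tertile"] = [s.tertile.value for s in self.scores]
        df["high_risk"] = [s.high_risk for s in self.scores]
        return df


def score_cohort(cohort: Cohort,
                 variant: CcrVariant | str = CcrVariant.AS_PRINTED,
                 cutoff: float = DEFAULT_CUTOFF,
                 cutpoints: tuple[float, float] = DEFAULT_TERTILE_CUTPOINTS,
                 ) -> ScoredCohort:
    """Score every record of a cohort."""
    variant = CcrVariant(variant)
    scores = tuple(sic_score(r, variant, cutoff, cutpoints) for r in cohort)
    return ScoredCohort(cohort=cohort, scores=scores, ccr_variant=variant)
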