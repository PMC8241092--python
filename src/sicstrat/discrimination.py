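"""Empirical ROC analysis with DeLong variance and paired AUC comparison.

The AUC is estimated by the Mann-Whitney statistic: the fraction of
case-control pairs in which the case outscores the control, ties counting
one half. Standard errors and the covariance between two AUCs measured on
the *same* patients come from the DeLong structural-component (placement
value) decomposition, computed with the midrank algorithm so large cohorts
stay O(n log n). The paired z test

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab)

is referred to the standard normal, two-sided — appropriate for cohorts of
the size this score targets (thousands); no small-sample correction is
applied.

Optimal cutoffs maximise the Youden index J = sensitivity + specificity - 1,
ties broken toward the smallest (most sensitive) cutoff, and the reported
cutoff is placed midway between the selected threshold and the next lower
observed score so it separates the same patients without sitting on a value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "RocCurve",
    "AucEstimate",
    "AucComparison",
    "empirical_roc",
    "auc_delong",
    "compare_auc_delong",
    "optimal_cutoff_youden",
]


def _as_arrays(score, label):
    s = np.asarray(score, dtype=float)
    y = np.asarray(label)
    if y.dtype != bool:
        y = y.astype(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("labels must be binary (0/1 or bool)")
        y = y.astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("score and label must be 1-D and aligned")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    if y.all() or (~y).all():
        raise DegenerateDataError(
            "both outcome classes must be present to assess discrimination")
    return s, y


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: descending thresholds (classify positive iff
    score >= threshold, leading +inf gives the (0, 1) corner)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    covariance: float
    z: float
    p: float


def empirical_roc(score, label) -> RocCurve:
    """ROC curve over the unique observed score values (ties grouped)."""
    s, y = _as_arrays(score, label)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    pos = s[y]
    neg = s[~y]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def _placements(score, label):
    """DeLong placement values. Returns (auc, V10 over cases, V01 over
    controls) using midranks, robust to ties."""
    s, y = _as_arrays(score, label)
    m = int(y.sum())
    n = int((~y).sum())
    r_all = stats.rankdata(s, method="average")
    r_pos = stats.rankdata(s[y], method="average")
    r_neg = stats.rankdata(s[~y], method="average")
    auc = (r_all[y].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[y] - r_pos) / n          # per-case placement
    v01 = 1.0 - (r_all[~y] - r_neg) / m   # per-control placement
    return auc, v10, v01


def _var(v, mean):
    # sample variance of placement values around the AUC
    if len(v) < 2:
        return 0.0
    return float(np.sum((v - mean) ** 2) / (len(v) - 1))


def auc_delong(score, label) -> AucEstimate:
    """AUC with DeLong standard error and normal 95% CI (clipped to [0,1])."""
    auc, v10, v01 = _placements(score, label)
    var = _var(v10, auc) / len(v10) + _var(v01, auc) / len(v01)
    se = math.sqrt(max(var, 0.0))
    lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    return AucEstimate(auc=float(auc), se=se,
                       ci95=(max(lo, 0.0), min(hi, 1.0)))


def compare_auc_delong(score_a, score_b, label) -> AucComparison:
    """Paired DeLong comparison of two scores measured on the same patients.

    Identical or order-equivalent scores give z = 0, p = 1 exactly.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("score_a and score_b must have the same length")
    auc_a, v10a, v01a = _placements(a, label)
    auc_b, v10b, v01b = _placements(b, label)
    m, n = len(v10a), len(v01a)
    var_a = _var(v10a, auc_a) / m + _var(v01a, auc_a) / n
    var_b = _var(v10b, auc_b) / m + _var(v01b, auc_b) / n
    cov = 0.0
    if m > 1:
        cov += float(np.sum((v10a - auc_a) * (v10b - auc_b)) / (m - 1)) / m
    if n > 1:
        cov += float(np.sum((v01a - auc_a) * (v01b - auc_b)) / (n - 1)) / n
    diff = auc_a - auc_b
    denom = var_a + var_b - 2.0 * cov
    if diff == 0.0:
        z = 0.0
    elif denom <= 0.0:
        z = math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(denom)
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a=float(auc_a), auc_b=float(auc_b),
                         covariance=cov, z=float(z), p=p)


def optimal_cutoff_youden(roc: RocCurve) -> tuple[float, float, float]:
    """Cutoff maximising the Youden index on an empirical ROC curve.

    Returns ``(cutoff, sensitivity, specificity)``. Ties in J are broken
    toward the smallest cutoff. The cutoff is reported as the midpoint
    between the winning threshold and the next lower observed score (the
    threshold itself when no lower score exists).
    """
    t = np.asarray(roc.thresholds, dtype=float)
    if len(t) < 2:
        raise DegenerateDataError("ROC curve has no observed thresholds")
    j = np.asarray(roc.sensitivity) + np.asarray(roc.specificity) - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # descending order: last = smallest
    thr = t[best]
    if best + 1 < len(t):
        cutoff = (thr + t[best + 1]) / 2.0
    else:
        cutoff = thr
    return float(cutoff), float(roc.sensitivity[best]), float(roc.specificity[best])
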