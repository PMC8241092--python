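"""Univariate logistic risk model, calibration, and reclassification.

A raw risk score (e.g. SIC) is turned into a predicted probability through a
univariate logistic regression, p = expit(a + b * score). Calibration of the
fitted probabilities is assessed with the Hosmer-Lemeshow test: patients are
ranked by predicted risk, split into g near-equal quantile bins (g = 10,
"deciles of risk"), and observed event counts are compared with expected
counts bin by bin,

    chi2 = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)),   df = g - 2.

The incremental value of a new score over an old one is quantified by the
category-free net reclassification improvement (NRI) — the net fraction of
events whose predicted risk rises plus the net fraction of non-events whose
predicted risk falls — and the integrated discrimination improvement (IDI),
the gain in mean predicted risk among events minus the gain among
non-events. Confidence intervals for both come from a seeded nonparametric
bootstrap (percentile, resampled within outcome classes so every replicate
keeps both classes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

try:  # warning class added in statsmodels 0.14
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

from .discrimination import _as_arrays
from .errors import ConvergenceError, ValidationError

__all__ = [
    "LogisticFit",
    "HlResult",
    "ReclassResult",
    "fit_logistic",
    "hosmer_lemeshow",
    "continuous_nri",
    "idi",
    "DEFAULT_BOOT_SEED",
]

DEFAULT_BOOT_SEED = 20100101


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    predicted: np.ndarray
    converged: bool

    def predict(self, score) -> np.ndarray:
        """expit(intercept + slope * score)."""
        from scipy.special import expit
        return expit(self.intercept + self.slope * np.asarray(score, float))


def fit_logistic(score, label) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression of a binary outcome
    on a score (Newton iterations, gradient norm below 1e-8 at the optimum).

    Raises
    ------
    ValidationError
        If the score is constant.
    ConvergenceError
        On perfect separation or non-convergence.
    """
    s, y = _as_arrays(score, label)
    if np.ptp(s) == 0:
        raise ValidationError("score is constant; logistic slope is undefined")
    X = sm.add_constant(s)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y.astype(float), X).fit(
                method="newton", disp=0, tol=1e-10, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning) as e:
            raise ConvergenceError(
                "logistic fit did not converge: perfect separation of the "
                "outcome by the score") from e
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    intercept, slope = res.params
    return LogisticFit(
        intercept=float(intercept), slope=float(slope),
        slope_se=float(res.bse[1]), slope_p=float(res.pvalues[1]),
        predicted=np.asarray(res.predict(X), dtype=float), converged=True)


@dataclass(frozen=True)
class HlResult:
    """Hosmer-Lemeshow bin table and test. ``bins`` columns: n, observed,
    expected, mean_predicted."""

    bins: pd.DataFrame
    chi2: float
    df: int
    p: float


def hosmer_lemeshow(predicted, label, g: int = 10,
                    method: str = "corrected") -> HlResult:
    """Hosmer-Lemeshow goodness-of-fit test on predicted probabilities.

    Quantile binning keeps tied predictions in one bin; bins whose expected
    count is zero are merged into their neighbour (with a warning).
    ``method='corrected'`` uses the variance-corrected denominator
    E(1 - E/n); ``'simple'`` uses (O-E)^2/E + (O-E)^2/(n-E).
    """
    p = np.asarray(predicted, dtype=float)
    _, y = _as_arrays(p, label)  # reuse label checks; p checked below
    if not ((p > 0) & (p < 1)).all():
        raise ValidationError("predicted probabilities must lie strictly in (0,1)")
    if g < 3:
        raise ValidationError(f"need at least 3 bins for a testable fit, got g={g}")
    if len(p) < 5 * g:
        warnings.warn(f"n={len(p)} is below the recommended 5 per-bin minimum "
                      f"times g={g}; the chi-square reference is unreliable")
    codes = pd.qcut(p, g, labels=False, duplicates="drop")
    tab = (pd.DataFrame({"p": p, "y": y.astype(float), "bin": codes})
           .groupby("bin", sort=True)
           .agg(n=("y", "size"), observed=("y", "sum"),
                expected=("p", "sum"), mean_predicted=("p", "mean")))
    # merge degenerate bins (expected 0 or n) upward so denominators stay positive
    while len(tab) > 1 and ((tab.expected <= 0) | (tab.expected >= tab.n)).any():
        warnings.warn("merging a degenerate Hosmer-Lemeshow bin")
        i = int(np.flatnonzero((tab.expected <= 0) | (tab.expected >= tab.n))[0])
        j = i - 1 if i > 0 else i + 1
        tab.iloc[j, :3] = tab.iloc[j, :3] + tab.iloc[i, :3]
        tab.iloc[j, 3] = tab.iloc[j, 2] / tab.iloc[j, 0]
        tab = tab.drop(tab.index[i])
    o, e, n = tab.observed.values, tab.expected.values, tab.n.values
    if method == "corrected":
        chi2 = float(np.sum((o - e) ** 2 / (e * (1.0 - e / n))))
    elif method == "simple":
        chi2 = float(np.sum((o - e) ** 2 / e + (o - e) ** 2 / (n - e)))
    else:
        raise ValidationError(f"unknown method {method!r}")
    df = len(tab) - 2
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return HlResult(bins=tab.reset_index(drop=True), chi2=chi2, df=df, p=pval)


@dataclass(frozen=True)
class ReclassResult:
    """NRI and/or IDI with bootstrap percentile CIs. Fields belonging to the
    measure not computed are None."""

    nri: float | None = None
    nri_event: float | None = None
    nri_nonevent: float | None = None
    nri_ci95: tuple[float, float] | None = None
    nri_p: float | None = None
    idi: float | None = None
    idi_ci95: tuple[float, float] | None = None
    idi_p: float | None = None
    n_boot: int = 0
    seed: int = 0


def _check_pair(pred_old, pred_new, label):
    po = np.asarray(pred_old, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    if po.shape != pn.shape:
        raise ValidationError("pred_old and pred_new must have the same length")
    _, y = _as_arrays(po, label)
    return po, pn, y


def _nri_point(po, pn, y):
    up, down = pn > po, pn < po
    ev, ne = y, ~y
    nri_e = float(up[ev].mean() - down[ev].mean())
    nri_ne = float(down[ne].mean() - up[ne].mean())
    return nri_e, nri_ne


def _idi_point(po, pn, y):
    return float((pn[y] - po[y]).mean() - (pn[~y] - po[~y]).mean())


def _boot_ci(stat, po, pn, y, n_boot, seed):
    """Percentile CI by class-stratified resampling; bit-for-bit reproducible
    for a given (seed, n_boot)."""
    rng = np.random.default_rng(seed)
    ev = np.flatnonzero(y)
    ne = np.flatnonzero(~y)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ev, len(ev)), rng.choice(ne, len(ne))])
        out[b] = stat(po[idx], pn[idx], y[idx])
    lo, hi = np.quantile(out, [0.025, 0.975])
    se = float(out.std(ddof=1))
    point = stat(po, pn, y)
    pval = float(2 * stats.norm.sf(abs(point) / se)) if se > 0 else (
        1.0 if point == 0 else 0.0)
    return (float(lo), float(hi)), pval


def continuous_nri(pred_old, pred_new, label,
                   n_boot: int = 1000, seed: int = DEFAULT_BOOT_SEED,
                   ) -> ReclassResult:
    """Category-free NRI of ``pred_new`` over ``pred_old``.

    Up/down moves are strict increases/decreases of predicted probability;
    ties count as neither. The total is the event component plus the
    non-event component, each bounded in [-1, 1].
    """
    po, pn, y = _check_pair(pred_old, pred_new, label)
    nri_e, nri_ne = _nri_point(po, pn, y)
    ci, pval = _boot_ci(lambda a, b, c: sum(_nri_point(a, b, c)),
                        po, pn, y, n_boot, seed)
    return ReclassResult(nri=nri_e + nri_ne, nri_event=nri_e,
                         nri_nonevent=nri_ne, nri_ci95=ci, nri_p=pval,
                         n_boot=n_boot, seed=seed)


def idi(pred_old, pred_new, label,
        n_boot: int = 1000, seed: int = DEFAULT_BOOT_SEED) -> ReclassResult:
    """Integrated discrimination improvement of ``pred_new`` over
    ``pred_old``: gain in discrimination slope (mean risk among events minus
    mean risk among non-events)."""
    po, pn, y = _check_pair(pred_old, pred_new, label)
    point = _idi_point(po, pn, y)
    ci, pval = _boot_ci(_idi_point, po, pn, y, n_boot, seed)
    return ReclassResult(idi=point, idi_ci95=ci, idi_p=pval,
                         n_boot=n_boot, seed=seed)
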