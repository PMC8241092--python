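"""Kaplan-Meier estimation, log-rank comparison, and Cox regression.

One-year mortality is analysed from admission, with administrative
censoring at 365 days; in-hospital deaths are events like any other. The
Kaplan-Meier product-limit estimator and the log-rank test are delegated to
lifelines. Cox proportional-hazards regression is fitted here directly by
Newton maximisation of the partial likelihood, because follow-up recorded
in whole days produces tied event times and both the Efron (default) and
Breslow tie corrections must be available. Convergence requires the
gradient infinity-norm to fall below 1e-8; monotone partial likelihoods
(e.g. a binary covariate perfectly separating survivors) are reported as
non-convergence rather than returning a diverging coefficient. Confidence
intervals and p-values are Wald-type from the inverse observed information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ConvergenceError, DegenerateDataError, ValidationError

__all__ = ["KmCurve", "CoxFit", "kaplan_meier", "log_rank", "cox_ph",
           "cox_score_test"]


def _check_surv(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    e = e.astype(bool) if e.dtype == bool else e.astype(float).astype(bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValidationError("time and event must be 1-D and aligned")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("times must be finite and >= 0")
    return t, e


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate. ``event_times`` lists distinct times with at
    least one event (ascending); the curve starts at 1 and drops only
    there. All-censored data gives empty arrays (S identically 1)."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def kaplan_meier(time, event) -> KmCurve:
    """Kaplan-Meier survival curve; censored observations reduce the
    at-risk count without producing drops."""
    t, e = _check_surv(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]]
    return KmCurve(event_times=times,
                   survival=surv.to_numpy(dtype=float),
                   at_risk=ev["at_risk"].to_numpy(dtype=float))


def log_rank(time, event, group) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups: returns (chi2, df, p)."""
    t, e = _check_surv(time, event)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValidationError("group must align with time")
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValidationError("log-rank needs at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


@dataclass(frozen=True)
class CoxFit:
    names: tuple[str, ...]
    coef: np.ndarray          # log hazard ratios
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray          # (p, 2) on the HR scale
    p: np.ndarray
    loglik: float
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hr,
            "hr_lo95": self.ci95[:, 0], "hr_hi95": self.ci95[:, 1],
            "p": self.p}, index=list(self.names))


def _prepare(time, event, covariates):
    t, e = _check_surv(time, event)
    if isinstance(covariates, pd.DataFrame):
        names = tuple(map(str, covariates.columns))
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    if X.shape[0] != len(t):
        raise ValidationError("covariates must have one row per subject")
    if not e.any():
        raise DegenerateDataError("no events; the partial likelihood is flat")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValidationError(
            f"constant covariate(s): {[names[j] for j in np.flatnonzero(const)]}")
    # center for numerical stability; coefficients are unchanged
    Xc = X - X.mean(axis=0)
    order = np.argsort(t, kind="stable")
    return t[order], e[order], Xc[order], names


def _partial_lik(beta, t, e, X, ties):
    """(loglik, gradient, hessian) of the Cox partial likelihood.

    Subjects are sorted by time ascending; risk-set sums are suffix sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; cancels in all ratios and, for
    # the log-likelihood, only shifts it by a constant per event
    # extended-precision accumulators: the gradient is a long sum of nearly
    # cancelling terms and plain float64 cumsums stall Newton around 1e-6
    w = np.exp(eta).astype(np.longdouble)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix (risk-set) sums: S*_cum[i] = sum over subjects with index >= i
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = np.longdouble(0.0)
    grad = np.zeros(p, dtype=np.longdouble)
    hess = np.zeros((p, p), dtype=np.longdouble)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = np.flatnonzero(e[i:j]) + i
        d = len(d_idx)
        if d > 0:
            ll += eta[d_idx].astype(np.longdouble).sum()
            grad += X[d_idx].sum(axis=0)
            S0, S1, S2 = s0[i], s1[i], s2[i]
            if ties == "breslow" or d == 1:
                ll -= d * np.log(S0)
                grad -= d * S1 / S0
                hess -= d * (S2 / S0 - np.outer(S1, S1) / S0 ** 2)
            else:  # efron
                D0 = w[d_idx].sum()
                D1 = wx[d_idx].sum(axis=0)
                D2 = wxx[d_idx].sum(axis=0)
                for k in range(d):
                    f = k / d
                    a0 = S0 - f * D0
                    a1 = S1 - f * D1
                    a2 = S2 - f * D2
                    ll -= np.log(a0)
                    grad -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1, a1) / a0 ** 2
        i = j
    return (float(ll), np.asarray(grad, dtype=float),
            np.asarray(hess, dtype=float))


def cox_ph(time, event, covariates, ties: str = "efron",
           tol: float = 1e-8, maxiter: int = 50) -> CoxFit:
    """Cox proportional-hazards fit by Newton iteration.

    Parameters
    ----------
    covariates
        DataFrame (named columns) or array of shape (n, p).
    ties
        'efron' (default; exact for the day-resolution ties this data has in
        the usual approximation hierarchy) or 'breslow'.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    t, e, X, names = _prepare(time, event, covariates)
    beta = np.zeros(X.shape[1])
    ll, grad, hess = _partial_lik(beta, t, e, X, ties)
    for _ in range(maxiter):
        if np.abs(grad).max() < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError("singular information matrix") from err
        # step halving keeps the partial likelihood monotone
        for _ in range(30):
            cand = beta + step
            ll_new, g_new, h_new = _partial_lik(cand, t, e, X, ties)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.ptp(X @ beta) > 20:
            # relative risks spanning more than exp(20) across the cohort:
            # the partial likelihood is monotone (separation) and Newton is
            # walking to infinity
            raise ConvergenceError(
                "monotone partial likelihood (coefficient diverging): a "
                "covariate perfectly separates the event ordering")
    else:
        raise ConvergenceError(f"Cox fit did not converge in {maxiter} iterations")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    zcrit = 1.959963984540054
    ci = np.exp(np.column_stack([beta - zcrit * se, beta + zcrit * se]))
    return CoxFit(names=names, coef=beta, se=se, hr=np.exp(beta), ci95=ci,
                  p=2 * stats.norm.sf(np.abs(z)), loglik=ll, converged=True)


def cox_score_test(time, event, covariates, ties: str = "breslow",
                   ) -> tuple[float, int, float]:
    """Score (Rao) test of beta = 0 in a Cox model: (chi2, df, p).

    With Breslow ties and a single binary group covariate this is the
    log-rank statistic (exactly so when event times are untied).
    """
    t, e, X, _ = _prepare(time, event, covariates)
    _, grad, hess = _partial_lik(np.zeros(X.shape[1]), t, e, X, ties)
    chi2 = float(grad @ np.linalg.solve(-hess, grad))
    df = X.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df))
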