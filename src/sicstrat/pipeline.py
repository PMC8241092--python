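"""End-to-end orchestration: score, stratify, evaluate, survive, report.

``run_pipeline`` reproduces the structure of a full score-validation
analysis on any cohort file (or in-memory cohort): per-outcome event-rate
tables with group comparisons, ROC/AUC with paired DeLong contrasts against
comparator scores, a univariate logistic risk model with Hosmer-Lemeshow
calibration, continuous NRI and IDI, decision curves, and Kaplan-Meier /
log-rank / Cox survival by SIC strata. All outputs are plain text (JSON +
delimited tables) and every number is reproducible from (input, config,
seed).
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import asdict, dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from . import calibration as cal
from . import decision_curve as dca
from . import discrimination as disc
from . import survival as surv
from .cohort import Cohort, FLAG_COLUMNS, derive_mace, read_cohort
from .errors import ConvergenceError, SicstratError, ValidationError
from .scores import (DEFAULT_CUTOFF, DEFAULT_TERTILE_CUTPOINTS, CcrVariant,
                     score_cohort)

__all__ = [
    "PipelineConfig",
    "EventRateTable",
    "event_rate_summary",
    "baseline_table",
    "univariate_screen",
    "ScreenResult",
    "run_pipeline",
    "percent_1dp",
]

_TABLE_OUTCOMES = ("stroke", "acute_heart_failure", "tvr", "dialysis",
                   "death", "mace", "ci_aki", "bleeding")


def percent_1dp(count: int, n: int) -> float:
    """Percentage rounded half-up to one decimal, table style."""
    if n <= 0:
        raise ValidationError("n must be positive")
    q = (Decimal(count) * 100 / Decimal(n)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


def _outcome_vector(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "mace":
        comps = ["stroke", "dialysis", "acute_heart_failure", "tvr"]
        sub = df[comps]
        if sub.isna().any().any():
            raise ValidationError("MACE components contain missing flags")
        return sub.astype(bool).any(axis=1).to_numpy()
    if outcome not in df.columns:
        raise ValidationError(f"unknown outcome {outcome!r}")
    col = df[outcome]
    if col.isna().any():
        raise ValidationError(f"outcome {outcome!r} contains missing flags")
    return col.astype(bool).to_numpy()


@dataclass(frozen=True)
class EventRateTable:
    """Per-outcome counts and one-decimal percentages, overall and per
    group, with a two-group chi-square (Fisher at small expected counts)."""

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _compare_groups(events_by_group: list[tuple[int, int]]) -> tuple[float, float, str]:
    """(statistic, p, method) comparing event proportions across groups."""
    tab = np.array([[e, n - e] for e, n in events_by_group])
    if tab[:, 0].sum() == 0 or tab[:, 1].sum() == 0:
        return 0.0, 1.0, "degenerate"
    expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return float(chi2), float(p), "chi-square"
    if len(events_by_group) == 2:
        odds, p = stats.fisher_exact(tab)
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p), "chi-square"


def event_rate_summary(cohort: Cohort,
                       outcomes: Sequence[str] = _TABLE_OUTCOMES,
                       by: str | None = "cohort_label") -> EventRateTable:
    """Event counts and one-decimal percentages, overall and per group.

    ``by`` names a grouping column of the cohort frame (None for overall
    only); with exactly two groups each outcome gets a chi-square test of
    proportions (Fisher exact when an expected cell falls below 5).
    """
    df = cohort.to_frame()
    groups: list[tuple[str, pd.DataFrame]] = []
    if by is not None and df[by].nunique() > 1:
        groups = [(str(k), g) for k, g in df.groupby(by, sort=False)]
    rows = []
    for outcome in outcomes:
        y = _outcome_vector(df, outcome)
        row: dict = {"outcome": outcome,
                     "count_all": int(y.sum()),
                     "pct_all": percent_1dp(int(y.sum()), len(y))}
        per_group = []
        for name, g in groups:
            yg = _outcome_vector(g, outcome)
            row[f"count_{name}"] = int(yg.sum())
            row[f"pct_{name}"] = percent_1dp(int(yg.sum()), len(yg))
            per_group.append((int(yg.sum()), len(yg)))
        if len(per_group) >= 2:
            stat, p, method = _compare_groups(per_group)
            row["stat"], row["p"], row["method"] = stat, p, method
        rows.append(row)
    return EventRateTable(pd.DataFrame(rows))


def baseline_table(cohort: Cohort, group: str,
                   variables: Sequence[str],
                   skewed: Sequence[str] = (),
                   categorical: Sequence[str] = ()) -> pd.DataFrame:
    """Two-group baseline comparison table.

    Normal-style variables are compared by the two-sample t test and shown
    as mean +/- sd; variables listed in ``skewed`` by the rank-sum test and
    shown as median (IQR); ``categorical`` ones by chi-square on the
    contingency table.
    """
    df = cohort.to_frame()
    levels = df[group].dropna().unique()
    if len(levels) != 2:
        raise ValidationError(
            f"grouping {group!r} must have exactly 2 levels, got {len(levels)}")
    a = df[df[group] == levels[0]]
    b = df[df[group] == levels[1]]
    rows = []
    for v in variables:
        row = {"variable": v}
        if v in categorical:
            tab = pd.crosstab(df[group], df[v])
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
            if tab.to_numpy().min() == tab.to_numpy().max() or np.isnan(chi2):
                chi2, p = 0.0, 1.0
            for name, g in ((levels[0], a), (levels[1], b)):
                cnt = int(pd.to_numeric(g[v]).sum()) if g[v].dtype != object else None
                row[f"summary_{name}"] = (
                    f"{cnt} ({percent_1dp(cnt, len(g))}%)" if cnt is not None
                    else "n/a")
            row["stat"], row["p"], row["method"] = float(chi2), float(p), "chi-square"
        elif v in skewed:
            xa, xb = a[v].astype(float), b[v].astype(float)
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                      use_continuity=False, method="asymptotic")
            for name, x in ((levels[0], xa), (levels[1], xb)):
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                row[f"summary_{name}"] = f"{med:.1f} ({q1:.1f}, {q3:.1f})"
            row["stat"], row["p"], row["method"] = float(u), float(p), "rank-sum"
        else:
            xa, xb = a[v].astype(float), b[v].astype(float)
            t, p = stats.ttest_ind(xa, xb, equal_var=True)
            if np.isnan(t):  # zero variance in both groups, equal means
                t, p = 0.0, 1.0
            for name, x in ((levels[0], xa), (levels[1], xb)):
                row[f"summary_{name}"] = f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"
            row["stat"], row["p"], row["method"] = float(t), float(p), "t-test"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreenResult:
    """Univariate screen followed by one multivariable logistic model."""

    univariate: pd.DataFrame     # candidate, or, p, selected, separated
    selected: tuple[str, ...]
    multivariable: pd.DataFrame  # adjusted odds ratios for the selected set


def univariate_screen(cohort: Cohort | pd.DataFrame,
                      candidates: Sequence[str],
                      outcome: str,
                      alpha: float = 0.05) -> ScreenResult:
    """Screen candidate predictors by univariate logistic regression at
    ``p < alpha``, then fit one multivariable model on the selected set.

    A candidate that perfectly separates the outcome is selected (its
    univariate evidence is maximal) and flagged; the multivariable fit then
    surfaces the separation as a :class:`ConvergenceError`.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    y = _outcome_vector(df, outcome).astype(float)
    rows = []
    for c in candidates:
        x = df[c].astype(float).to_numpy()
        try:
            fit = cal.fit_logistic(x, y)
            rows.append({"candidate": c, "or": float(np.exp(fit.slope)),
                         "p": fit.slope_p, "separated": False,
                         "selected": fit.slope_p < alpha})
        except ConvergenceError:
            rows.append({"candidate": c, "or": float("inf"), "p": 0.0,
                         "separated": True, "selected": True})
    uni = pd.DataFrame(rows)
    selected = tuple(uni.loc[uni.selected, "candidate"])
    if not selected:
        return ScreenResult(uni, selected, pd.DataFrame())
    X = sm.add_constant(df[list(selected)].astype(float).to_numpy())
    import warnings as _w
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    with _w.catch_warnings():
        _w.simplefilter("error", cal.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", disp=0, tol=1e-10,
                                     maxiter=100)
        except (PerfectSeparationError, cal.PerfectSeparationWarning) as e:
            raise ConvergenceError(
                "multivariable logistic fit did not converge: perfect "
                f"separation among selected candidates {selected}") from e
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("multivariable logistic fit did not converge")
    ci = res.conf_int()[1:]
    multi = pd.DataFrame({
        "candidate": list(selected),
        "adjusted_or": np.exp(res.params[1:]),
        "or_lo95": np.exp(ci[:, 0]),
        "or_hi95": np.exp(ci[:, 1]),
        "p": res.pvalues[1:]})
    return ScreenResult(uni, selected, multi)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; YAML/JSON-loadable via ``from_file``."""

    input_path: str | None = None
    schema: Mapping[str, str] = field(default_factory=dict)
    ccr_variant: str = CcrVariant.AS_PRINTED.value
    sic_cutoff: float = DEFAULT_CUTOFF
    tertile_cutpoints: tuple[float, float] = DEFAULT_TERTILE_CUTPOINTS
    outcomes: tuple[str, ...] = ("death", "mace", "ci_aki", "bleeding")
    comparator_scores: tuple[str, ...] = ("si100", "ccr")
    boot_seed: int = cal.DEFAULT_BOOT_SEED
    n_boot: int = 1000
    hl_bins: int = 10
    dca_thresholds: tuple[float, ...] = tuple(dca.DEFAULT_THRESHOLDS)
    time_col: str = "followup_days"
    event_col: str = "death_1y"
    adjust: tuple[str, ...] = ()
    out_dir: str = "sicstrat_out"

    def __post_init__(self) -> None:
        lo, hi = self.tertile_cutpoints
        if not lo < hi:
            raise ValidationError("tertile cutpoints must be strictly increasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        for k in ("tertile_cutpoints", "outcomes", "comparator_scores",
                  "dca_thresholds", "adjust"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        return cls(**data)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def _evaluate_outcome(df: pd.DataFrame, outcome: str,
                      cfg: PipelineConfig) -> dict:
    y = _outcome_vector(df, outcome)
    sic = df["sic"].to_numpy()
    out: dict = {"outcome": outcome, "n": len(y), "events": int(y.sum())}
    est = disc.auc_delong(sic, y)
    out["auc_sic"] = {"auc": est.auc, "se": est.se, "ci95": list(est.ci95)}
    roc = disc.empirical_roc(sic, y)
    cut, sens, spec = disc.optimal_cutoff_youden(roc)
    out["youden"] = {"cutoff": cut, "sensitivity": sens, "specificity": spec}

    fit_sic = cal.fit_logistic(sic, y)
    hl = cal.hosmer_lemeshow(fit_sic.predicted, y, g=cfg.hl_bins)
    out["hosmer_lemeshow"] = {"chi2": hl.chi2, "df": hl.df, "p": hl.p,
                              "bins": hl.bins}
    curves = [dca.net_benefit(fit_sic.predicted, y,
                              np.array(cfg.dca_thresholds)).to_frame("sic")]

    out["comparators"] = {}
    for comp in cfg.comparator_scores:
        s = pd.to_numeric(df[comp]).to_numpy(dtype=float)
        fit_c = cal.fit_logistic(s, y)
        # evaluate on the fitted-probability scale so inversely oriented
        # scores (e.g. creatinine clearance, protective) compare fairly
        comp_auc = disc.auc_delong(fit_c.predicted, y)
        cmp_ = disc.compare_auc_delong(sic, fit_c.predicted, y)
        nri = cal.continuous_nri(fit_c.predicted, fit_sic.predicted, y,
                                 n_boot=cfg.n_boot, seed=cfg.boot_seed)
        idi_ = cal.idi(fit_c.predicted, fit_sic.predicted, y,
                       n_boot=cfg.n_boot, seed=cfg.boot_seed)
        curves.append(dca.net_benefit(fit_c.predicted, y,
                                      np.array(cfg.dca_thresholds)).to_frame(comp))
        out["comparators"][comp] = {
            "auc": {"auc": comp_auc.auc, "se": comp_auc.se,
                    "ci95": list(comp_auc.ci95)},
            "delong": {"z": cmp_.z, "p": cmp_.p},
            "nri": {"nri": nri.nri, "ci95": list(nri.nri_ci95), "p": nri.nri_p},
            "idi": {"idi": idi_.idi, "ci95": list(idi_.idi_ci95), "p": idi_.idi_p},
        }
    out["_dca"] = pd.concat(curves, ignore_index=True)
    return out


def _survival_block(df: pd.DataFrame, cfg: PipelineConfig) -> dict:
    t = df[cfg.time_col].astype(float).to_numpy()
    e = df[cfg.event_col].astype(bool).to_numpy()
    out: dict = {}
    for grouping in ("tertile", "high_risk"):
        g = df[grouping].astype(str).to_numpy()
        chi2, dfree, p = surv.log_rank(t, e, g)
        out[grouping] = {"log_rank_chi2": chi2, "df": dfree, "p": p, "km": {}}
        for level in sorted(pd.unique(g)):
            m = g == level
            km = surv.kaplan_meier(t[m], e[m])
            out[grouping]["km"][level] = {
                "n": int(m.sum()),
                "deaths": int(e[m].sum()),
                "event_times": km.event_times,
                "survival": km.survival,
            }
    cov = pd.DataFrame({"sic_gt_cutoff": df["high_risk"].astype(float)})
    for c in cfg.adjust:
        cov[c] = pd.to_numeric(df[c]).astype(float)
    fit = surv.cox_ph(t, e, cov)
    out["cox_high_risk"] = fit.summary().reset_index(names="covariate")
    return out


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns the in-memory report dictionary. Writes: scored.csv,
    event_rates.csv, dca_<outcome>.csv, report.json, run.log. Identical
    (input, config) always produces an identical bundle (timestamps only in
    the log).
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        log.append(f"[{_time.strftime('%Y-%m-%dT%H:%M:%S')}] {name}")

    try:
        stage("read")
        if cohort is None:
            if config.input_path is None:
                raise ValidationError("no cohort given and no input_path configured")
            cohort = read_cohort(config.input_path, schema=config.schema)
        stage("score")
        scored = score_cohort(cohort, variant=config.ccr_variant,
                              cutoff=config.sic_cutoff,
                              cutpoints=tuple(config.tertile_cutpoints))
        df = scored.to_frame()
        df.to_csv(outdir / "scored.csv", index=False)
        report: dict = {"config": _jsonify(asdict(config)),
                        "n": len(df),
                        "strata_n": {"tertile": df["tertile"].value_counts().to_dict(),
                                     "high_risk": df["high_risk"].sum().item()}}
        stage("event rates")
        rates = event_rate_summary(cohort)
        rates.table.to_csv(outdir / "event_rates.csv", index=False)
        report["event_rates"] = rates.table
        stage("discrimination/calibration/reclassification/decision curves")
        report["outcomes"] = {}
        for outcome in config.outcomes:
            res = _evaluate_outcome(df, outcome, config)
            res.pop("_dca").to_csv(outdir / f"dca_{outcome}.csv", index=False)
            report["outcomes"][outcome] = res
        stage("survival")
        has_fu = (config.time_col in df.columns
                  and df[config.time_col].notna().all()
                  and config.event_col in df.columns
                  and df[config.event_col].notna().all())
        if has_fu:
            report["survival"] = _survival_block(df, config)
        else:
            log.append("  follow-up columns incomplete: survival stage skipped")
            report["survival"] = None
    except SicstratError as e:
        log.append(f"  ABORT: {e}")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        raise
    (outdir / "report.json").write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True))
    stage("done")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return report
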