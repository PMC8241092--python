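# Methods

This note documents the statistical procedures the package implements, the
defaults it ships, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The score

SIC = 100·SI − CCr with SI = HR/SBP. Two creatinine-clearance estimates
are offered:

- `as_printed` (default): CCr = (140 − age)/Scr, × 0.85 for women. This
  weight-free abbreviation reproduces the cohort-level mean clearance the
  score was derived with (≈ 80 mL/min at age ~61, Scr ~1.0), so it is the
  default.
- `full_cockcroft_gault`: (140 − age)·weight/(72·Scr), × 0.85 for women;
  requires body weight, and equals the printed form exactly at 72 kg.

Whether the score's originators truly used the weight-free form cannot be
settled from the published text; both are provided and the choice is a
config switch everywhere downstream.

Stratification uses full-precision SIC values (no rounding). Tertile
boundaries are left-closed on the upper strata (−30 → T2, −5 → T3), so the
three intervals partition the line; the binary rule is strictly
SIC > cutoff (default 10), i.e. the cutoff value itself is low-risk. MACE
is the union of stroke, dialysis, acute heart failure, and TVR; death is
accounted separately and deliberately excluded from the composite, matching
the way the source tables tally the two rows independently.

## Discrimination

AUC is the Mann-Whitney estimator (ties count ½). Variances, and the
covariance between two AUCs on the same patients, use the DeLong
structural-component decomposition computed from midranks (O(n log n),
tie-robust). The paired test is z = ΔAUC/√(var_a + var_b − 2cov) against
the standard normal, two-sided; no small-sample correction is applied —
the intended cohorts have thousands of patients, and the test suite
documents the approximation by checking the null rejection rate at n = 200.
Order-identical scores short-circuit to z = 0, p = 1.

Youden-optimal cutoffs maximise sensitivity + specificity − 1, with ties
broken toward the smallest (most sensitive) cutoff; the reported cutoff is
the midpoint between the winning threshold and the next lower observed
score, so it separates the same patients without sitting on an observed
value.

## Calibration and reclassification

A raw score becomes a probability through a univariate logistic fit
(Newton, gradient norm < 1e-8; perfect separation raises instead of
returning runaway coefficients). Hosmer-Lemeshow uses quantile binning
(g = 10 by default, ties kept together, degenerate bins merged with a
warning), the statistic Σ(O−E)²/(E(1−E/n)), and a χ²(g−2) reference. The
df = 8 behaviour at g = 10 is what makes the published chi-square/p pairs
internally consistent. Note the "simpler" spelling Σ(O−E)²/E + Σ(O−E)²/(n−E)
is algebraically the same number; both names are accepted in config and a
test asserts the identity.

NRI is the category-free (continuous) variant — no risk categories were
ever published for this score — counting strict up/down moves of predicted
probability; ties count neither. IDI is the difference in discrimination
slopes. Confidence intervals come from a nonparametric bootstrap
(percentile, default 1,000 resamples, default seed 20100101), resampled
*within* outcome classes so every replicate retains both classes;
reproducible bit-for-bit given (seed, n_boot). The p-values attached to
NRI/IDI use a normal approximation with the bootstrap SE. Whether the
published CIs were bootstrap or asymptotic is not stated anywhere; the
bootstrap was chosen as the assumption-light default.

## Decision curves

Net benefit NB(t) = TP/n − FP/n · t/(1−t) on a default grid 0.01–0.50 in
steps of 0.01 (the clinically plausible range for in-hospital mortality
decisions; no grid was published). Classification at exactly t is
inclusive (predicted ≥ t treated). Raw scores are first mapped to
probabilities through their univariate logistic fits so SI, CCr, and SIC
are comparable on the probability scale — this also fixes the orientation
of protective scores such as CCr, and the pipeline evaluates comparator
AUCs on the same fitted-probability scale for the same reason.

## Survival

The 1-year clock starts at admission, includes in-hospital deaths, and is
administratively censored at day 365. Kaplan-Meier and the log-rank test
are delegated to lifelines. Cox regression is an in-package Newton solver
on the partial likelihood because day-resolution follow-up creates tied
event times and both Efron (default) and Breslow corrections were wanted;
lifelines (Efron-only) serves as the independent cross-check in the tests.
Numerics: risk-set suffix sums are accumulated in extended precision
(float64 cumsums leave a ~1e-6 gradient floor that stalls Newton below the
1e-8 convergence tolerance); covariates are centered; a linear-predictor
spread above exp(20) is reported as monotone-likelihood non-convergence
(separation) rather than returning a diverging coefficient. Wald CIs and
p-values come from the inverse observed information. The two-group
log-rank statistic equals the Breslow score test at β = 0 (exactly so
without ties), which the tests verify numerically.

The covariate set behind any "adjusted" hazard ratio is user-specified
config — no adjustment set was ever enumerated for this score, so nothing
is hard-coded.

## Synthetic cohorts

The generator emulates the published population, not any real patient:

- Covariates: age, heart rate, SBP, weight are truncated normals
  (age ∈ [18, 120), vitals > 20, weight > 20) at the published mean ± sd
  (61.4 ± 12.3 y, 80.2 ± 16.1 bpm, 121.4 ± 22.0 mmHg, 65.3 ± 10.9 kg);
  sex is Bernoulli(0.828 male); creatinine is log-normal with median 1.0
  and σ_log chosen so the IQR is 0.8–1.2 mg/dL, truncated above 0.2.
  Covariates are drawn independently — only marginals were published — so
  the generated SIC distribution is near-normal where the real one need
  not be (tertile sizes differ somewhat from the published 584/567/700).
- Outcomes: each in-hospital flag is Bernoulli(expit(a + b·SIC)). The
  link (a, b) is *calibrated* on a pilot sample of 50,000: b by 1-D root
  finding so the expected Mann-Whitney AUC of SIC for the outcome (a
  closed-form function of the per-patient probabilities) hits its target —
  0.87 for death, the published SIC AUCs for CI-AKI (0.707) and bleeding
  (0.732), and the composite's 0.837 for the four MACE components — and a
  so the expected prevalence hits the published rate. The pilot uses a
  fixed internal seed: the link is part of the generative model, and the
  cohort seed should drive sampling only.
- The MACE flag is always *derived* from its components, never drawn.
  Because components are conditionally independent given SIC while the
  real ones co-occur, the derived composite rate lands near 11% rather
  than the published 9.6%; this is a documented consequence of modelling
  only what was printed.
- Follow-up: exponential with hazard h₀·exp(β·(SIC − mean SIC)), censored
  at 365 d. Defaults h₀ = 1e-4/day and β = 0.026 were chosen once so the
  crude tertile-3 vs tertile-1 hazard ratio is near 8 (the magnitude of
  the published adjusted HR) and overall 1-year mortality is a plausible
  ~5%; these are illustrative, not inferential. In-hospital death and
  1-year death are drawn from their own links, so a patient can carry one
  flag without the other — the generator makes no joint claim the source
  data never supported.

A green test on synthetic data therefore establishes that the *methods*
behave correctly in a world with the published marginals and effect sizes;
it cannot establish anything about the real cohort's joint structure.

## Tables and pipeline

Event-rate tables report counts and percentages rounded half-up to one
decimal (table style); percentages always recompute exactly from their own
counts. Two-group comparisons use the chi-square test without continuity
correction (matching the large-sample behaviour of the original analyses),
falling back to Fisher's exact test when an expected cell drops below 5.
Baseline tables use t tests for normal-style variables, rank-sum (no
continuity correction, so duplicated groups give p = 1 exactly) for skewed
ones, chi-square for categorical ones. The univariate screen enters every
candidate with univariate p < 0.05 into a single multivariable logistic
model (single-step entry; no stepwise refinement), and a perfectly
separating candidate is selected and then surfaced as a convergence error
by the multivariable fit.

`run_pipeline` is deterministic for fixed (input, config): all randomness
(bootstraps) flows from the configured seed, and re-running a config
rewrites a byte-identical `report.json`.

## Known limitations

- No covariate correlations or treatment variables in the generator; no
  derivation/validation drift.
- No multi-category NRI, no recalibration methods, no confidence bands on
  net benefit, no time-varying covariates or competing risks.
- Comparator scores (GRACE, TIMI, CRUSADE, Mehran) are accepted only as
  precomputed columns; their formulas are out of scope.
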