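"""Calibration (Hosmer-Lemeshow) and incremental value (NRI/IDI) of SIC.

SIC is turned into a predicted death probability with a univariate
logistic model; calibration compares observed vs expected deaths across
deciles of risk. NRI/IDI quantify what SIC adds over SI alone.
"""

from sicstrat import (GeneratorConfig, continuous_nri, fit_logistic,
                      generate_cohort, hosmer_lemeshow, idi, score_cohort)

df = score_cohort(generate_cohort(GeneratorConfig(seed=7))).to_frame()
y = df.death.astype(bool).to_numpy()

fit_sic = fit_logistic(df.sic.to_numpy(), y)
hl = hosmer_lemeshow(fit_sic.predicted, y, g=10)
print(f"Hosmer-Lemeshow chi2 = {hl.chi2:.2f} on {hl.df} df, p = {hl.p:.3f}")
print("(large p = no evidence of miscalibration across risk deciles)\n")

fit_si = fit_logistic(df.si100.to_numpy(), y)
nri = continuous_nri(fit_si.predicted, fit_sic.predicted, y)
res_idi = idi(fit_si.predicted, fit_sic.predicted, y)
print(f"continuous NRI = {100 * nri.nri:.1f}% "
      f"(95% CI {100 * nri.nri_ci95[0]:.1f} to {100 * nri.nri_ci95[1]:.1f})")
print(f"IDI            = {100 * res_idi.idi:.1f}% "
      f"(95% CI {100 * res_idi.idi_ci95[0]:.1f} to "
      f"{100 * res_idi.idi_ci95[1]:.1f})")
print("\nPositive NRI/IDI: switching from SI to SIC moves events toward "
      "higher predicted risk and non-events toward lower.")
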