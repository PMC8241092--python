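"""One-year mortality by SIC stratum: Kaplan-Meier, log-rank, Cox.

The clock starts at admission; follow-up is administratively censored at
365 days. High SIC should carry a large hazard for 1-year death.
"""

import numpy as np
import pandas as pd

from sicstrat import (GeneratorConfig, cox_ph, generate_cohort, kaplan_meier,
                      log_rank, score_cohort)

df = score_cohort(generate_cohort(GeneratorConfig(seed=7))).to_frame()
t = df.followup_days.to_numpy()
e = df.death_1y.astype(bool).to_numpy()

print("1-year survival by SIC tertile:")
for tert in ("T1", "T2", "T3"):
    m = (df.tertile == tert).to_numpy()
    km = kaplan_meier(t[m], e[m])
    s365 = km.survival[-1] if len(km.survival) else 1.0
    print(f"  {tert}: n={m.sum():4d}  deaths={e[m].sum():3d}  "
          f"S(365d) = {s365:.3f}")

chi2, dfree, p = log_rank(t, e, df.tertile.to_numpy())
print(f"log-rank chi2 = {chi2:.1f} on {dfree} df, p = {p:.2g}")

cov = pd.DataFrame({"sic_gt_10": df.high_risk.astype(float),
                    "age": df.age.astype(float)})
fit = cox_ph(t, e, cov)
row = fit.summary().loc["sic_gt_10"]
print(f"Cox: SIC>10 adjusted HR = {row.hr:.2f} "
      f"(95% CI {row.hr_lo95:.2f}-{row.hr_hi95:.2f}), p = {row.p:.2g}")

print("\nMortality concentrates in the top tertile; SIC>10 multiplies the "
      "1-year death hazard several-fold even after age adjustment.")
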