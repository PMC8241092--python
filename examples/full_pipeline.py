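"""Run the complete validation pipeline and inspect the report bundle.

One call scores the cohort, tabulates event rates, evaluates
discrimination/calibration/reclassification per outcome, computes decision
curves, and runs the survival analyses; everything lands as plain-text
tables and JSON in the output directory.
"""

from sicstrat import (GeneratorConfig, PipelineConfig, generate_cohort,
                      run_pipeline)

cohort = generate_cohort(GeneratorConfig(n=1851, seed=7))
report = run_pipeline(PipelineConfig(out_dir="pipeline_out"), cohort=cohort)

print("report bundle written to pipeline_out/\n")
print("event rates (overall):")
print(report["event_rates"][["outcome", "count_all", "pct_all"]]
      .to_string(index=False))

d = report["outcomes"]["death"]
print(f"\ndeath: AUC(SIC) {d['auc_sic']['auc']:.3f}, "
      f"HL p {d['hosmer_lemeshow']['p']:.3f}, "
      f"Youden cutoff {d['youden']['cutoff']:.1f}")
for comp, r in d["comparators"].items():
    print(f"  vs {comp:<6} AUC {r['auc']['auc']:.3f}  "
          f"DeLong p {r['delong']['p']:.2g}  "
          f"NRI {100 * r['nri']['nri']:.0f}%  IDI {100 * r['idi']['idi']:.1f}%")

s = report["survival"]["tertile"]
print(f"\n1-year mortality, tertile log-rank chi2 = {s['log_rank_chi2']:.1f} "
      f"(p = {s['p']:.2g})")
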