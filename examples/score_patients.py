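"""Compute the Shock Index-C for a handful of admissions.

SIC = 100 * (heart rate / systolic BP) - estimated creatinine clearance;
higher is worse. Tertiles split at -30 and -5; SIC > 10 flags high risk.
"""

from sicstrat import PatientRecord, sic_score

patients = [
    PatientRecord("stable", age=55, sex="male", heart_rate=68, sbp=135, scr=0.9),
    PatientRecord("borderline", age=60, sex="male", heart_rate=80, sbp=120, scr=1.0),
    PatientRecord("shocked", age=75, sex="female", heart_rate=110, sbp=90, scr=1.5),
]

print(f"{'patient':<12}{'SIx100':>8}{'CCr':>8}{'SIC':>8}  stratum")
for p in patients:
    s = sic_score(p)
    flag = "HIGH RISK" if s.high_risk else s.tertile.value
    print(f"{p.patient_id:<12}{s.si100:>8.1f}{s.ccr:>8.1f}{s.sic:>8.1f}  {flag}")

print("\nA negative SIC means renal clearance outweighs the shock index "
      "(low risk); the shocked patient scores far above the +10 cutoff.")
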