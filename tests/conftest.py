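import numpy as np
import pytest

from sicstrat import Cohort, PatientRecord


def make_record(i=0, **kw):
    """A valid record with sensible defaults, overridable per test."""
    base = dict(patient_id=f"p{i}", age=60.0, sex="male", heart_rate=80.0,
                sbp=120.0, scr=1.0, weight=70.0)
    base.update(kw)
    return PatientRecord(**base)


@pytest.fixture
def small_cohort():
    recs = [
        make_record(0, age=55, heart_rate=72, sbp=130, scr=0.9,
                    death=False, stroke=False, acute_heart_failure=False,
                    dialysis=False, tvr=False, ci_aki=False, bleeding=False,
                    followup_days=365.0, death_1y=False),
        make_record(1, age=71, sex="female", heart_rate=95, sbp=100, scr=1.4,
                    weight=None, death=True, stroke=False,
                    acute_heart_failure=True, dialysis=False, tvr=False,
                    ci_aki=True, bleeding=False, followup_days=12.0,
                    death_1y=True),
        make_record(2, age=63, heart_rate=88, sbp=118, scr=1.1,
                    death=False, stroke=True, acute_heart_failure=False,
                    dialysis=False, tvr=False, ci_aki=False, bleeding=True,
                    followup_days=365.0, death_1y=False),
    ]
    return Cohort(tuple(recs), label="fixture")


def printed_table2_cohort():
    """Cohort of 1,851 records whose outcome flags reproduce the published
    in-hospital event counts, split 1,145 derivation / 706 validation.

    Component flags overlap deliberately so the derived MACE composite
    matches its published counts (101 and 77): the published components sum
    to more than the composite because events co-occur.
    """
    def build(n, label, dialysis_n, ahf_range, stroke_range, tvr_range,
              death_n, ciaki_n, bleed_n):
        recs = []
        for i in range(n):
            recs.append(PatientRecord(
                patient_id=f"{label[0]}{i:05d}", age=60.0, sex="male",
                heart_rate=80.0, sbp=120.0, scr=1.0,
                dialysis=i < dialysis_n,
                acute_heart_failure=ahf_range[0] <= i < ahf_range[1],
                stroke=stroke_range[0] <= i < stroke_range[1],
                tvr=tvr_range[0] <= i < tvr_range[1],
                death=i < death_n,
                ci_aki=i < ciaki_n,
                bleeding=i < bleed_n,
                cohort_label=label))
        return recs

    # derivation: dialysis 34, AHF 68 (20 overlap), stroke 13, TVR 6 -> MACE 101
    deriv = build(1145, "derivation", 34, (14, 82), (82, 95), (95, 101),
                  40, 115, 126)
    # validation: dialysis 36, AHF 50 (25 overlap), stroke 10, TVR 6 -> MACE 77
    valid = build(706, "validation", 36, (11, 61), (61, 71), (71, 77),
                  28, 70, 67)
    return Cohort(tuple(deriv + valid), label="printed-counts")


@pytest.fixture(scope="session")
def table2_cohort():
    return printed_table2_cohort()
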