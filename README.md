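# empirx

Rule-based clinical decision support for **empirical antibiotic therapy**,
together with the **antimicrobial-stewardship evaluation** used to measure
how such a system is adopted after implementation.

The package is for clinical informaticians and stewardship researchers who
want a testable, declarative engine rather than a hospital-bound web
application: guideline flowcharts live in a published YAML schema, every
binding rule (culture windows, eGFR freshness, renal dose bands) is
explicit code, and a seeded synthetic cohort generator makes the whole
pipeline reproducible without patient data.

## What it does

* **Knowledge base** (`empirx.knowledge_base`) — load, lint and enumerate
  declarative diagnosis flowcharts (questions → obligatory
  antibiogram-review gate → advice) and per-drug dose tables banded on
  eGFR. The lint reports violations as data: unreachable nodes, cycles,
  paths that never reach an advice, uncovered dose bands.
* **Advisor engine** (`empirx.advisor`) — interactive sessions that
  auto-answer questions bound to patient data (pregnancy, IgE allergy,
  neutropenia), enforce the culture-review gate, deviate from the first
  choice on documented resistance (R) or matching allergy class, and
  resolve doses by renal function, pregnancy and (ideal) body weight.
  Includes CURB-65, Devine ideal body weight and BMI calculators. For a
  severity assessment: CURB-65 = confusion + (urea > 7 mmol/L)
  + (RR ≥ 30) + (SBP < 90 or DBP ≤ 60) + (age ≥ 65), risk
  low/moderate/high at 0–1 / 2 / ≥3.
* **Stewardship evaluation** (`empirx.stewardship`) — cohort filters (ATC
  J01, adults, >1-day admissions), the prophylaxis definitions (<48 h,
  cotrimoxazole 480 mg, perioperative cefazolin, SDD/neutropenia/COPD
  protocols, post-splenectomy pheneticillin), complete/partial/none
  adherence classification, proportional stratified sampling with Wald
  binomial intervals, and the eligibility → usage → adoption report.
* **Synthetic cohorts** (`empirx.synthetic`) — seeded generation of
  patients, prescriptions, cultures and engine-driven sessions with known
  ground truth.

## Worked example

```python
from datetime import date, datetime
from empirx import (example_kb, start_session, submit_answer,
                    acknowledge_gate, generate_advice, PatientRecord)
from empirx.patient_data import Observation

kb = example_kb()
patient = PatientRecord(
    patient_id="DEMO", birth_date=date(1950, 4, 2), sex="male",
    ward="pulmonology",
    admission_start=datetime(2017, 2, 27, 14), admission_end=datetime(2017, 3, 8, 11),
    weight_kg=82, height_cm=178,
    observations=[Observation(kind="egfr", value=42.0,
                              observed_at=datetime(2017, 2, 28, 8))],
)
s = start_session(kb, patient, "pneumonia", datetime(2017, 3, 1, 10))
submit_answer(s, "hospital")   # the allergy question auto-answers itself
acknowledge_gate(s)            # obligatory antibiogram review
advice = generate_advice(s)
for d in advice.drugs:
    print(d.drug, d.dose.dose_amount, d.dose.dose_unit, d.route,
          f"q{d.dose.interval_hours}h")
```

prints

```
piperacillin-tazobactam 4.5 g iv q12h
```

— hospital-acquired pneumonia resolves to piperacillin-tazobactam, and the
patient's eGFR of 42 mL/min/1.73 m² falls in the [30, 50) band, so the
12-hourly row is chosen instead of the 8-hourly one. With a prior culture
resistant to piperacillin-tazobactam on file, the same session instead
returns ceftriaxone with a recorded `resistance` deviation. The
`examples/` directory walks through validation, advice generation, the
full stewardship evaluation and the calculators, each printing and
explaining its output.

There is also a thin CLI: `empirx validate-kb`, `empirx advise`,
`empirx evaluate`, `empirx simulate`, `empirx example-kb` (see
`empirx --help`).

The example knowledge base is **illustrative, not clinical guidance**:
its topology and first-choice drugs follow common empirical patterns but
dose amounts and thresholds are placeholders. File formats are documented
in `docs/kb_schema.md` and `docs/cohort_schema.md`; the modelling choices
in `docs/methods.md`.

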