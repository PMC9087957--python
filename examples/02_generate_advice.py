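"""Walk the pneumonia pathway for one patient and print the advice.

The engine auto-answers questions bound to patient data (here the
IgE-allergy question), stops at the obligatory antibiogram-review gate,
and refines the terminal regimen by renal function. A second run adds a
prior culture resistant to the first choice, triggering a deviation to the
first conflict-free alternative.
"""

from datetime import date, datetime

from empirx import (
    PatientRecord,
    acknowledge_gate,
    example_kb,
    generate_advice,
    start_session,
    submit_answer,
)
from empirx.patient_data import CultureResult, Observation

kb = example_kb()
NOW = datetime(2017, 3, 1, 10, 0)

patient = PatientRecord(
    patient_id="DEMO",
    birth_date=date(1950, 4, 2),
    sex="male",
    ward="pulmonology",
    admission_start=datetime(2017, 2, 27, 14, 0),
    admission_end=datetime(2017, 3, 8, 11, 0),
    weight_kg=82,
    height_cm=178,
    observations=[Observation(kind="egfr", value=42.0,
                              observed_at=datetime(2017, 2, 28, 8, 0))],
)

session = start_session(kb, patient, "pneumonia", NOW)
submit_answer(session, "hospital")      # acquired in hospital -> HAP branch
# the allergy question answered itself from the (empty) allergy list:
print("trail so far:", [(e.node_id, e.answer, e.source)
                        for e in session.answer_trail])
acknowledge_gate(session)               # obligatory antibiogram review
print("cultures shown at the gate:", session.attached_cultures)

advice = generate_advice(session)
for d in advice.drugs:
    print(f"advice: {d.drug} {d.dose.dose_amount} {d.dose.dose_unit} "
          f"{d.route} q{d.dose.interval_hours}h for {advice.duration_days} days")
# eGFR 42 falls in the [30, 50) band -> the 12-hourly row, not the 8-hourly one

# same consult, but a recent culture resistant to piperacillin-tazobactam
patient2 = patient.model_copy(update={"cultures": [CultureResult(
    specimen="sputum", collected_at=datetime(2017, 1, 20, 9, 0),
    organism="Escherichia coli",
    antibiogram={"piperacillin-tazobactam": "R", "ceftriaxone": "S"},
)]})
session = start_session(kb, patient2, "pneumonia", NOW)
submit_answer(session, "hospital")
acknowledge_gate(session)
advice = generate_advice(session)
print("\nwith documented resistance:",
      advice.drug_ids, "| deviation:", advice.deviation)
# the engine deviates to ceftriaxone, recording reason 'resistance'
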