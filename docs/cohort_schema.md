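# Cohort extract schema

The canonical exchange format is JSON lines: one patient object per line
(`cohort.jsonl`). Unknown fields are rejected. Timestamps are ISO 8601;
dates are `YYYY-MM-DD`.

```json
{
  "patient_id": "P00001",
  "birth_date": "1952-03-08",
  "sex": "female",
  "ward": "internal_medicine",
  "admission_start": "2017-01-12T09:00:00",
  "admission_end": "2017-01-20T12:00:00",
  "weight_kg": 71.5,
  "height_cm": 166.0,
  "pregnant": false,
  "allergies": [{"drug_class": "penicillin", "ige_mediated": true}],
  "observations": [
    {"kind": "egfr", "value": 64.0, "observed_at": "2017-01-12T11:00:00"},
    {"kind": "neutrophils", "value": 3.8, "observed_at": "2017-01-12T11:00:00"}
  ],
  "cultures": [
    {"specimen": "urine", "collected_at": "2016-11-02T08:00:00",
     "organism": "Escherichia coli",
     "antibiogram": {"nitrofurantoin": "R", "ciprofloxacin": "S"}}
  ],
  "prescriptions": [
    {"atc": "J01MA02", "drug": "ciprofloxacin", "dose_amount": 400,
     "dose_unit": "mg", "route": "iv", "interval_hours": 12,
     "start": "2017-01-13T10:00:00", "stop": "2017-01-20T10:00:00"}
  ],
  "diagnoses": ["urinary_tract_infection"]
}
```

Field notes:

* `observations.kind` is `egfr` (mL/min/1.73 m²) or `neutrophils`
  (10⁹/L); values are non-negative. eGFR is an extracted observation —
  the package never computes it from creatinine.
* `cultures.antibiogram` maps drug id → `S`/`I`/`R`; an antibiogram is
  required whenever an organism is present.
* `prescriptions` carry optional stewardship fields:
  `perioperative_context` (`pre`/`intra`/`post`), `clear_indication`
  (manual assessment for perioperative cefazolin), `protocol_tag`
  (`sdd`/`neutropenia`/`copd`/`post_splenectomy`) and `splenectomy_date`.
  `stop >= start` is enforced; `interval_hours` is needed for
  dosage-regimen adherence comparison.
* `diagnoses` are working-diagnosis labels used only by the stewardship
  evaluation (eligibility), never by the advisor engine.

## CSV bundle

A directory with `patients.csv` plus optional `observations.csv`,
`cultures.csv`, `prescriptions.csv` is accepted by the same reader. Child
tables reference `patient_id`. Composite fields are flattened:

* `patients.csv` — `allergies` as `class|ige;class|ige` (ige ∈ {0,1}),
  `diagnoses` as a `;`-joined list;
* `cultures.csv` — `antibiogram` as `drug:code;drug:code`.

## Sessions file

`sessions.jsonl` stores one recorded CDSS use per line:

```json
{"session_id": "S-P00001", "patient_id": "P00001",
 "diagnosis": "urinary_tract_infection", "at_time": "2017-01-13T09:00:00",
 "is_test": false, "advice": { ... AdviceOutcome ... }}
```

`is_test` marks try-out uses (excluded from the usage numerator);
`advice` is the engine's outcome (regimen with per-drug dose decisions, or
a consult referral) including the answer trail.
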