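"""Clinical calculators and renal/weight-aware dose selection.

CURB-65 grades pneumonia severity (the answer to the pathway's risk-level
question); the Devine ideal body weight drives per-kilogram gentamicin
dosing; dose tables resolve a concrete dose per eGFR band or fall back to
an infectious-disease consult.
"""

from empirx import (
    ClinicalMeasures,
    WeightContext,
    bmi,
    curb65,
    example_kb,
    ideal_body_weight,
    select_dose,
)

m = ClinicalMeasures(confusion=False, urea=9.1, respiratory_rate=32,
                     systolic_bp=110, diastolic_bp=70, age=71)
score, risk = curb65(m)
print(f"CURB-65: score {score}, {risk} risk")
# urea > 7, respiratory rate >= 30 and age >= 65 each score a point -> high

ibw = ideal_body_weight("male", 180)
print(f"ideal body weight (male, 180 cm): {ibw:.1f} kg; "
      f"BMI at 95 kg: {bmi(95, 180):.1f} kg/m²")

kb = example_kb()
ctx = WeightContext(sex="male", height_cm=180, weight_kg=95)
for egfr in (85, 40, 20, 5):
    d = select_dose("gentamicin", kb, egfr=egfr, weight_ctx=ctx)
    if d.consult:
        print(f"eGFR {egfr:>3}: consult infectious-disease specialist "
              f"({d.rationale})")
    else:
        print(f"eGFR {egfr:>3}: gentamicin {d.dose_amount} {d.dose_unit} "
              f"q{d.interval_hours}h (ideal weight {d.weight_used.kg} kg)")
# 5 mg/kg of ideal weight; the interval stretches as eGFR falls and the
# lowest band refers to the specialist instead of guessing
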