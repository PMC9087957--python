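# Methods

## Problem and model

`empirx` implements a rule-based clinical decision support system (CDSS)
for empirical antibiotic therapy in adult hospitalized patients, plus the
descriptive stewardship evaluation used to assess such a system after
implementation. The CDSS is a set of declarative guideline flowcharts:
for each working diagnosis (sepsis, pneumonia, urinary tract infection,
fever of unknown origin, meningitis, secondary peritonitis, liver
abscess) a rooted directed acyclic chart of questions leads, through an
obligatory antibiogram-review gate, to a terminal advice — a concrete
regimen (drugs, dose, route, interval, duration) or a referral to the
infectious-disease specialist. Charts are DAGs rather than trees because
answers may converge (e.g. moderate- and high-risk community-acquired
pneumonia share a branch).

Two refinement stages act on the terminal regimen:

* **Deviation.** If a culture from the review window documents resistance
  (R) to a first-choice drug, or an allergy matches a drug's class, the
  engine substitutes the first declared alternative regimen free of both
  conflicts; with none available the advice becomes a consult. Intermediate
  (I) results do not trigger deviation by default (`if necessary` is read
  conservatively); a flag treats I as R for stricter sites. When both a
  resistance and an allergy conflict exist, the recorded reason is
  `resistance` (the culture is the stronger, patient-specific evidence).
* **Dose selection.** Per-drug tables are banded on eGFR with half-open
  `[lo, hi)` bands jointly covering `[0, ∞)`, so exactly one band matches
  any value — half-open intervals remove boundary ambiguity. A band may be
  a renal contraindication (consult). Pregnancy-disallowed rows, absent
  weight data for weight-based dosing, or a missing fresh eGFR for a
  renally banded table all resolve to a consult marker: the engine never
  guesses a dose.

## Data-binding and freshness rules

Questions may bind to patient data and answer themselves (trail source
`auto`): pregnancy (always asked manually when unset and the patient is
female; auto-answered `no` for males), IgE-mediated allergy, neutropenia
(absolute neutrophil count < 0.5 × 10⁹/L), and age ≥ 65. Manual answers
may override automatic ones; the trail keeps both, because extracted data
can be missing or outdated.

Freshness windows are fixed integers to make behaviour exact and testable:
an eGFR is usable only if determined strictly less than 7 days (7 × 24 h)
before the consultation; "previous 6 months" for cultures is 183 days; the
neutrophil binding applies the same 7-day window as eGFR (data recency was
a stated design concern for both values, though the explicit rule is
stated only for eGFR — this is the package's own harmonization).

## Clinical calculators

* **CURB-65**: one point each for confusion, urea > 7 mmol/L, respiratory
  rate ≥ 30/min, systolic BP < 90 or diastolic ≤ 60 mmHg, age ≥ 65; risk
  low (0–1), moderate (2), high (≥3). The pneumonia pathway asks for the
  risk level; the calculator answers it.
* **Ideal body weight** (Devine): 50 kg (male) / 45.5 kg (female)
  + 0.9055 kg/cm above 152.4 cm, floored at the base value. Gentamicin
  dosing is per kg of ideal weight.
* **BMI**: kg/m².

## Stewardship evaluation

Cohort filters: adults (≥ 18 y at admission), admission > 1 day, at least
one systemic antibacterial (ATC prefix `J01`, case-sensitive), at least
one non-prophylactic J01 course.

Prophylaxis rules, applied first-match in a fixed order: any course
shorter than 48 h; cotrimoxazole at 480 mg; cefazolin started pre-,
intra- or postoperatively without another clear indication (an explicit
boolean input — "clear indication" needs human assessment, so the package
never infers it); the SDD, neutropenia and COPD protocol tags;
pheneticillin within 2 years (fixed at 730 days) after splenectomy.

Adherence, per advice, over systemic antibacterials started within a
24-hour window after the advice (the chart-review original states no
window; a fixed one makes the classifier deterministic): **complete** —
every advised drug prescribed with matching route and dosage regimen
(dose amount and interval after unit normalization, g ↔ mg); **partial**
— at least one advised drug prescribed, but a drug missing or a
route/regimen differing; **none** — no advised drug prescribed. Drugs
whose advised dose is a consult marker match on drug and route only.
Ambiguity is never resolved by guessing: the outcome carries the per-drug
match detail (`matched` / `mismatched` fields / `missing`).

Statistics: eligibility is estimated on a proportional stratified random
sample (strata = wards; largest-remainder rounding so stratum counts sum
exactly to n; uniform sampling without replacement within strata; fully
seeded). The confidence interval is the Wald interval clipped to
[0, 100] — the simplest method consistent with a symmetric interval; no
claim is made that any particular published interval used the same
method. The extrapolated eligible count is
`floor(n_cohort × round(k/n_sample, 3))`; with a 100/248 sample over a
3349-patient cohort this yields 1349. Usage is
`100 × (sessions − test sessions) / extrapolated eligible`. The adherence
rate counts complete + partial over all clinical uses (consult advices
included in the denominator) and is truncated — not rounded — to one
decimal, matching the convention of the source statistics (114/169 =
67.455 → 67.4); other percentages use ordinary rounding.

## Synthetic cohort generator

The generator emulates the statistical structure the evaluation assumes,
with defaults set to the study-like conditions: 3349 patients across 7
ward strata; 15% prophylaxis-only patients (each realized by one
rule-matching course); among the rest, 40.3% carry a CDSS-included
diagnosis (pneumonia and urinary tract infection most frequent); 12.5% of
eligible patients generate a real advisor session; try-out sessions are
added at a per-patient probability calibrated so their expected share of
all sessions is 15/184; 44.4% of patients are female; 10% of eligible
patients have a prior culture resistant to their diagnosis's first-choice
drug (driving deviations). Sessions run the real engine (manual questions
answered uniformly at random, gates acknowledged); for each regimen
advice an intended adherence category is drawn from the configured
mixture (default the observed 91:23:55 of 169) and realized as
prescriptions: complete copies the advice; partial drops one drug or
changes one drug's route or dose with equal probability; none prescribes
a non-advised drug. Ground truth records every intended label.

Randomness is one seeded root sequence, stream-split per patient, so
adding or removing a patient never changes another patient's draws and
identical configs are byte-identical.

What the generator does **not** emulate: real microbiology epidemiology
(one organism, a small fixed antibiogram panel), correlated
comorbidities, length-of-stay/diagnosis dependence, physicians' actual
answer behaviour (answers are uniform over legal options), or incomplete
EHR extraction. Passing tests therefore demonstrate correctness of the
engine and evaluation machinery under the configured statistical
structure, not clinical validity on real hospital data.

## Numerical and design choices

* The example knowledge base is **illustrative**: the pathway topology
  and drug choices follow common empirical patterns, but dose amounts and
  eGFR thresholds are placeholders (standard band structure ≥50, 30–50,
  10–30, <10), and dose tables are keyed per drug, not per drug+route.
* Question nodes declare their legal answer set; the lint checks edges
  against it, so any deleted edge is detectable even where answers
  converge.
* `load_kb` rejects only unresolvable references; everything else is a
  lint violation, so broken-but-parseable charts (the realistic bug
  class: a path with no generated advice at the end, a wrong threshold)
  can be reported as data.
* Alternative regimens are tried strictly in declared order (first fit);
  no re-ranking by antibiogram beyond that.
* The 500-replicate coverage check of the Wald interval samples repeatedly
  from one generated cohort rather than regenerating cohorts; the
  statistical content (coverage of the configured 40% prevalence at
  n = 248) is unchanged and the check runs in seconds.
* Problem sizes in the test suite (cohorts of 500–3349, ~2000 engine-driven
  sessions for mixture recovery, 10,000 random prescriptions for the
  prophylaxis oracle, 100+ knowledge-base mutations) were chosen to give
  3-standard-error resolution on the recovered parameters while keeping
  the whole suite in the tens of seconds.

## Known limitations

* No drug–drug interaction checking, pediatric dosing, or therapeutic
  drug monitoring.
* Allergy matching is by drug class only; cross-reactivity between
  classes (e.g. penicillins vs cephalosporins) is not modelled.
* The evaluation is descriptive; no causal claim about the CDSS's effect
  on prescribing quality is computed.
* eGFR is consumed as an observation, never derived from creatinine.
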