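# Knowledge-base file schema

A knowledge base is a YAML mapping (JSON, being a YAML subset, is accepted
by the same loader). This document is normative for the artifact; the
shipped example content is illustrative, not clinical guidance.

```yaml
version: "example-1"
diagnoses:
  <diagnosis name>:
    root: <node id>
    nodes:
      <node id>: <decision node>
dose_rules:
  <drug id>: <dose rule table>
```

## Decision nodes

Every node has a `kind`: `question`, `gate` or `advice`.

### question

```yaml
q_acquired:
  kind: question
  prompt: "Where was the pneumonia acquired?"
  answers: [community, hospital]     # declared legal answers
  edges: {hospital: q_allergy_hap, community: q_curb}
  data_binding: null                 # optional, see below
```

* `edges` maps each answer value to the next node id; the lint requires the
  edge keys to cover the declared `answers` exactly (`answers` defaults to
  the edge keys when omitted) and at least two distinct answers.
* `data_binding` names a patient-record binding that can answer the
  question automatically: `pregnant`, `ige_allergy`, `neutropenic`,
  `age_65_plus`. A binding that cannot resolve (value missing, or stale per
  the freshness rules) leaves the question manual. Manual answers may
  override automatic ones; the session trail records both.

### gate

```yaml
gate_hap:
  kind: gate
  gate_kind: antibiogram_review
  window_days: 183      # cultures from the previous 6 months
  next: adv_hap
```

A gate is a mandatory stop: the clinician must acknowledge the review of
the antibiogram of previous cultures before the traversal proceeds. It has
exactly one successor (`next`).

### advice

Either a regimen or a referral to the infectious-disease specialist:

```yaml
adv_hap:
  kind: advice
  regimen:
    drugs: [{drug: piperacillin-tazobactam, route: iv}]
    duration_days: 7
    alternatives:                     # ranked; used for deviation
      - {drugs: [{drug: ceftriaxone, route: iv}], duration_days: 7}
adv_consult:
  kind: advice
  consult: true
```

`route` is `iv` or `oral`. `duration_days` may be an integer or a
two-element `[lo, hi]` range. `alternatives` are tried in order when a
first-choice drug carries a documented R result in the windowed cultures
or matches an allergy drug class; if none is conflict-free the advice
becomes a consult.

## Dose rule tables

```yaml
gentamicin:
  drug_class: aminoglycoside      # allergy matching
  fallback: consult
  rows:
    - {egfr_min: 50, dose_amount: 5, dose_unit: mg/kg, interval_hours: 24,
       weight_basis: ideal, pregnancy_allowed: false}
    - {egfr_min: 30, egfr_max: 50, dose_amount: 5, dose_unit: mg/kg,
       interval_hours: 36, weight_basis: ideal, pregnancy_allowed: false}
    - {egfr_min: 10, egfr_max: 30, dose_amount: 5, dose_unit: mg/kg,
       interval_hours: 48, weight_basis: ideal, pregnancy_allowed: false}
    - {egfr_min: 0, egfr_max: 10, consult: true}
```

* Bands are half-open `[egfr_min, egfr_max)` in mL/min/1.73 m²; omitted
  `egfr_max` means unbounded. The lint requires non-overlapping bands that
  jointly cover `[0, inf)`.
* A row with `consult: true` expresses a renal contraindication; the
  table-level `fallback: consult` applies when no row is usable (for
  example a pregnancy-disallowed row for a pregnant patient).
* `weight_basis: ideal` resolves the per-kg dose through the Devine ideal
  body weight; `actual` uses the recorded weight; with a `dose_unit`
  ending in `/kg` the emitted dose is the resolved total.
* A renally banded table with no fresh eGFR (determined less than 7 days
  before the consult) resolves to the consult marker, never a guess.

## Referential rules

`load_kb` rejects files whose `root`, question edges or gate `next` point
to undefined nodes, naming the offending path. All other well-formedness
rules (acyclicity, reachability, termination in an advice node, answer
completeness, dose-table presence for every advised drug including
alternatives, band coverage) are reported by `validate_kb` as a list of
violations with rule ids.
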