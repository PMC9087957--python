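"""Stewardship evaluation: cohort filters, prophylaxis and adherence
classification, proportional stratified sampling, and the summary report.

The evaluation mirrors a descriptive implementation study: adult patients
(excluding 1-day admissions) with at least one systemic antibacterial (ATC
J01) form the cohort; prophylaxis-only patients are excluded. CDSS
eligibility is estimated on a proportional stratified random sample of the
cohort and extrapolated; usage and adherence rates are computed from the
advisor sessions and the prescriptions that followed them.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .advisor import AdviceOutcome
from .patient_data import PatientRecord, Prescription, age_at, is_systemic_antibacterial

INCLUDED_DIAGNOSES = frozenset(
    {
        "sepsis",
        "pneumonia",
        "urinary_tract_infection",
        "fever_of_unknown_origin",
        "meningitis",
        "secondary_peritonitis",
        "liver_abscess",
    }
)

#: prophylaxis rules in classification order (first match wins)
PROPHYLAXIS_RULES = (
    "duration_lt_48h",
    "cotrimoxazole_480",
    "perioperative_cefazolin",
    "sdd",
    "neutropenia",
    "copd",
    "pheneticillin_post_splenectomy",
)

SPLENECTOMY_WINDOW_DAYS = 730  # "within 2 years after splenectomy"


class ProphylaxisCall(BaseModel):
    model_config = ConfigDict(extra="forbid")

    is_prophylaxis: bool
    rule: Literal[
        "duration_lt_48h",
        "cotrimoxazole_480",
        "perioperative_cefazolin",
        "sdd",
        "neutropenia",
        "copd",
        "pheneticillin_post_splenectomy",
        "none",
    ]


def _rule_matches(rule: str, rx: Prescription, patient: PatientRecord) -> bool:
    if rule == "duration_lt_48h":
        return rx.stop is not None and rx.stop - rx.start < timedelta(hours=48)
    if rule == "cotrimoxazole_480":
        return (
            rx.drug == "cotrimoxazole"
            and rx.dose_unit == "mg"
            and rx.dose_amount == 480
        )
    if rule == "perioperative_cefazolin":
        return (
            rx.drug == "cefazolin"
            and rx.perioperative_context is not None
            and not rx.clear_indication
        )
    if rule in ("sdd", "neutropenia", "copd"):
        return rx.protocol_tag == rule
    if rule == "pheneticillin_post_splenectomy":
        spl = rx.splenectomy_date
        return (
            rx.drug == "pheneticillin"
            and spl is not None
            and timedelta(0)
            <= rx.start.date() - spl
            <= timedelta(days=SPLENECTOMY_WINDOW_DAYS)
        )
    raise ValueError(f"unknown rule {rule!r}")


def classify_prophylaxis(rx: Prescription, patient: PatientRecord) -> ProphylaxisCall:
    """Classify one prescription against the prophylaxis definitions.

    Rules are evaluated in a fixed order (short course, cotrimoxazole
    480 mg, perioperative cefazolin without clear indication, the SDD /
    neutropenia / COPD protocols, pheneticillin within two years of
    splenectomy); the first matching rule is reported.
    """
    for rule in PROPHYLAXIS_RULES:
        if _rule_matches(rule, rx, patient):
            return ProphylaxisCall(is_prophylaxis=True, rule=rule)
    return ProphylaxisCall(is_prophylaxis=False, rule="none")


def filter_cohort(cohort: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Apply the evaluation inclusion filters.

    Keeps adult patients (>= 18 years at admission) admitted for more than
    one day with at least one systemic antibacterial (J01) prescription of
    which at least one is not prophylactic.
    """
    out = []
    for p in cohort:
        if age_at(p.birth_date, p.admission_start) < 18:
            continue
        if p.admission_end - p.admission_start <= timedelta(days=1):
            continue
        j01 = [rx for rx in p.prescriptions if is_systemic_antibacterial(rx.atc)]
        if not j01:
            continue
        if all(classify_prophylaxis(rx, p).is_prophylaxis for rx in j01):
            continue
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# adherence


class AdherenceOutcome(BaseModel):
    model_config = ConfigDict(extra="forbid")

    category: Literal["complete", "partial", "none"]
    #: advised drugs prescribed with fully matching route and dosage regimen
    matched: list[str] = Field(default_factory=list)
    #: advised drugs prescribed but with a different route or dosage regimen
    mismatched: dict[str, list[str]] = Field(default_factory=dict)
    #: advised drugs not prescribed at all
    missing: list[str] = Field(default_factory=list)


_MASS_MG = {"mg": 1.0, "g": 1000.0}


def _normalize_dose(amount: float, unit: str | None) -> tuple[float, str | None]:
    if unit in _MASS_MG:
        return amount * _MASS_MG[unit], "mg"
    return amount, unit


def _regimen_mismatches(advised, rx: Prescription) -> list[str]:
    """Fields on which a same-drug prescription deviates from the advice."""
    fields = []
    if rx.route != advised.route:
        fields.append("route")
    dose = advised.dose
    if dose.consult:
        return fields  # dose unspecified (consult marker): match on drug+route only
    adv_amount, adv_unit = _normalize_dose(dose.dose_amount, dose.dose_unit)
    rx_amount, rx_unit = _normalize_dose(rx.dose_amount, rx.dose_unit)
    if (adv_amount, adv_unit) != (rx_amount, rx_unit):
        fields.append("dose")
    if dose.interval_hours is not None and rx.interval_hours != dose.interval_hours:
        fields.append("interval")
    return fields


def classify_adherence(
    advice: AdviceOutcome,
    prescriptions: Sequence[Prescription],
    advice_time: datetime,
    window_hours: int = 24,
) -> AdherenceOutcome:
    """Classify prescriptions against an advice as complete / partial / none.

    Only systemic antibacterials started within ``window_hours`` after the
    advice are considered. Complete: every advised drug prescribed with
    matching route and dosage regimen (dose amount and interval after unit
    normalization). Partial: at least one advised drug prescribed, but a
    drug missing or a route/regimen differing. None: no advised drug
    prescribed. Consult advices are not classifiable.
    """
    if advice.kind != "regimen":
        raise ValueError("a consult advice has no regimen to adhere to")
    hi = advice_time + timedelta(hours=window_hours)
    window_rx = [
        rx
        for rx in prescriptions
        if is_systemic_antibacterial(rx.atc) and advice_time <= rx.start <= hi
    ]
    matched: list[str] = []
    mismatched: dict[str, list[str]] = {}
    missing: list[str] = []
    for advised in advice.drugs:
        same_drug = [rx for rx in window_rx if rx.drug == advised.drug]
        if not same_drug:
            missing.append(advised.drug)
            continue
        per_rx = [_regimen_mismatches(advised, rx) for rx in same_drug]
        best = min(per_rx, key=len)
        if best:
            mismatched[advised.drug] = best
        else:
            matched.append(advised.drug)
    if not matched and not mismatched:
        category = "none"
    elif not mismatched and not missing:
        category = "complete"
    else:
        category = "partial"
    return AdherenceOutcome(
        category=category, matched=matched, mismatched=mismatched, missing=missing
    )


# ---------------------------------------------------------------------------
# sampling and statistics


def proportional_stratified_sample(
    cohort: Sequence[PatientRecord],
    n: int,
    seed: int,
    stratum: Callable[[PatientRecord], str] = lambda p: p.ward,
) -> list[PatientRecord]:
    """Proportional stratified random sample (strata default to wards).

    Per-stratum counts follow largest-remainder rounding so that they sum
    exactly to ``n``; within a stratum, sampling is uniform without
    replacement. Fully reproducible from ``seed``.
    """
    if n > len(cohort):
        raise ValueError(f"sample size {n} exceeds cohort size {len(cohort)}")
    groups: dict[str, list[PatientRecord]] = {}
    for p in cohort:
        groups.setdefault(stratum(p), []).append(p)
    total = len(cohort)
    quotas = {s: n * len(g) / total for s, g in groups.items()}
    counts = {s: math.floor(q) for s, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        groups, key=lambda s: (-(quotas[s] - counts[s]), s)
    )
    for s in by_remainder[:leftover]:
        counts[s] += 1
    rng = np.random.default_rng(seed)
    sample: list[PatientRecord] = []
    for s in sorted(groups):
        members = sorted(groups[s], key=lambda p: p.patient_id)
        take = min(counts[s], len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        sample.extend(members[i] for i in sorted(idx))
    return sample


def proportion_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Wald binomial confidence interval, on the percentage scale.

    Returns ``(point, lower, upper)`` in percent, clipped to [0, 100].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return (
        100 * p,
        max(0.0, 100 * (p - half)),
        min(100.0, 100 * (p + half)),
    )


def extrapolate_eligible(n_cohort: int, k: int, n_sample: int) -> int:
    """Extrapolated eligible count: floor of cohort size times the sample
    proportion rounded to three decimals."""
    return math.floor(n_cohort * round(k / n_sample, 3))


def usage_rate_pct(n_sessions_total: int, n_sessions_test: int, n_eligible: int) -> float:
    """CDSS usage among eligible patients, in percent (test uses excluded)."""
    if n_eligible <= 0:
        raise ValueError("n_eligible must be positive")
    return 100.0 * (n_sessions_total - n_sessions_test) / n_eligible


def trunc1(x: float) -> float:
    """Truncate to one decimal (the convention used for the adherence rate)."""
    return math.floor(x * 10) / 10


def adherence_rate_pct(n_complete: int, n_partial: int, n_advice: int) -> float:
    """Share of advices followed completely or partly, truncated to one decimal."""
    if n_advice <= 0:
        raise ValueError("n_advice must be positive")
    return trunc1(100.0 * (n_complete + n_partial) / n_advice)


# ---------------------------------------------------------------------------
# session records and the evaluation report


class SessionRecord(BaseModel):
    """One recorded CDSS use, as stored in sessions.jsonl."""

    model_config = ConfigDict(extra="forbid")

    session_id: str
    patient_id: str
    diagnosis: str
    at_time: datetime
    is_test: bool = False
    advice: AdviceOutcome | None = None


def read_sessions(path: str | Path) -> list[SessionRecord]:
    with Path(path).open() as fh:
        return [
            SessionRecord.model_validate_json(line)
            for line in fh
            if line.strip()
        ]


def write_sessions(sessions: Sequence[SessionRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sessions:
            fh.write(s.model_dump_json(exclude_none=True) + "\n")


class EvaluationReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cohort: int
    n_sample: int
    k_eligible: int
    eligibility_pct: float
    eligibility_ci_low_pct: float
    eligibility_ci_high_pct: float
    n_eligible_extrapolated: int
    n_sessions_total: int
    n_sessions_test: int
    usage_pct: float
    n_advice: int
    n_regimen_advice: int
    n_consult_advice: int
    n_complete: int
    n_partial: int
    n_none: int
    adherence_followed_pct: float
    female_pct: float | None = None
    usage_by_diagnosis: dict[str, int] = Field(default_factory=dict)
    usage_by_ward: dict[str, int] = Field(default_factory=dict)

    def to_text(self) -> str:
        """Plain-text flow table: uses -> test uses -> advices -> adherence."""
        rows = [
            ("cohort (J01, non-prophylactic)", self.n_cohort),
            (f"eligible (extrapolated, {self.eligibility_pct:.1f}% "
             f"[{self.eligibility_ci_low_pct:.1f}, {self.eligibility_ci_high_pct:.1f}])",
             self.n_eligible_extrapolated),
            ("CDSS uses", self.n_sessions_total),
            ("  test / try-out uses", self.n_sessions_test),
            (f"  clinical uses ({self.usage_pct:.1f}% of eligible)", self.n_advice),
            ("    antibiotic advice (dose and route)", self.n_regimen_advice),
            ("    advice: consult ID specialist", self.n_consult_advice),
            (f"  followed ({self.adherence_followed_pct:.1f}%)",
             self.n_complete + self.n_partial),
            ("    completely", self.n_complete),
            ("    partly", self.n_partial),
            ("    not followed", self.n_none),
        ]
        width = max(len(label) for label, _ in rows)
        return "\n".join(f"{label.ljust(width)}  {count:>6}" for label, count in rows)


def evaluate(
    cohort: Sequence[PatientRecord],
    sessions: Sequence[SessionRecord],
    sample_n: int,
    seed: int,
    included_diagnoses: frozenset[str] = INCLUDED_DIAGNOSES,
    window_hours: int = 24,
) -> EvaluationReport:
    """Assemble the stewardship evaluation report.

    ``cohort`` must already be filtered (:func:`filter_cohort`). Eligibility
    is estimated from a proportional stratified sample using the patients'
    recorded diagnosis labels, then extrapolated to the cohort. Usage
    excludes test sessions; adherence is classified per regimen advice
    against the patient's prescriptions in the post-advice window, and the
    adherence rate denominator is all clinical uses (consults included).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    by_id = {p.patient_id: p for p in cohort}

    sample = proportional_stratified_sample(cohort, sample_n, seed)
    k_eligible = sum(
        1 for p in sample if included_diagnoses & set(p.diagnoses)
    )
    point, lo, hi = proportion_ci(k_eligible, len(sample))
    n_extrapolated = extrapolate_eligible(len(cohort), k_eligible, len(sample))

    real = [s for s in sessions if not s.is_test]
    n_test = len(sessions) - len(real)
    usage = (
        usage_rate_pct(len(sessions), n_test, n_extrapolated)
        if sessions and n_extrapolated > 0
        else 0.0
    )

    n_regimen = n_consult = n_complete = n_partial = n_none = 0
    by_diagnosis: dict[str, int] = {}
    by_ward: dict[str, int] = {}
    n_female = 0
    for s in real:
        patient = by_id.get(s.patient_id)
        by_diagnosis[s.diagnosis] = by_diagnosis.get(s.diagnosis, 0) + 1
        if patient is not None:
            by_ward[patient.ward] = by_ward.get(patient.ward, 0) + 1
            n_female += patient.sex == "female"
        if s.advice is None:
            continue
        if s.advice.kind == "consult_id":
            n_consult += 1
            continue
        n_regimen += 1
        if patient is None:
            continue
        outcome = classify_adherence(
            s.advice, patient.prescriptions, s.at_time, window_hours
        )
        if outcome.category == "complete":
            n_complete += 1
        elif outcome.category == "partial":
            n_partial += 1
        else:
            n_none += 1

    n_advice = len(real)
    return EvaluationReport(
        n_cohort=len(cohort),
        n_sample=len(sample),
        k_eligible=k_eligible,
        eligibility_pct=round(point, 1),
        eligibility_ci_low_pct=round(lo, 1),
        eligibility_ci_high_pct=round(hi, 1),
        n_eligible_extrapolated=n_extrapolated,
        n_sessions_total=len(sessions),
        n_sessions_test=n_test,
        usage_pct=round(usage, 1),
        n_advice=n_advice,
        n_regimen_advice=n_regimen,
        n_consult_advice=n_consult,
        n_complete=n_complete,
        n_partial=n_partial,
        n_none=n_none,
        adherence_followed_pct=(
            adherence_rate_pct(n_complete, n_partial, n_advice) if n_advice else 0.0
        ),
        female_pct=round(100 * n_female / n_advice, 1) if n_advice else None,
        usage_by_diagnosis=dict(sorted(by_diagnosis.items())),
        usage_by_ward=dict(sorted(by_ward.items())),
    )
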