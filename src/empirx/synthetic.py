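"""Seeded synthetic cohort generator.

Generates patient records, advisor sessions and ground-truth labels that
emulate the statistical structure of a CDSS implementation study: ward
strata, a configurable prevalence of CDSS-included diagnoses among patients
on systemic antibacterials, a configurable complete/partial/none adherence
mixture realized against the example knowledge base's own advice,
prophylaxis-only patients, prior cultures resistant to the first-choice
drug, and try-out (test) sessions.

Randomness comes from one seeded generator per run, stream-split per
patient, so inserting or removing a patient does not change any other
patient's draws.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .advisor import (
    AdviceOutcome,
    AdvisedDrug,
    QuestionNode,
    Session,
    acknowledge_gate,
    generate_advice,
    start_session,
    submit_answer,
)
from .drugs import atc_for
from .kb_fixture import example_kb
from .knowledge_base import KnowledgeBase, dump_kb
from .patient_data import (
    Allergy,
    CultureResult,
    Observation,
    PatientRecord,
    Prescription,
)
from .stewardship import SessionRecord

DEFAULT_WARD_WEIGHTS = {
    "internal_medicine": 0.30,
    "surgery": 0.20,
    "pulmonology": 0.15,
    "urology": 0.10,
    "neurology": 0.10,
    "intensive_care": 0.10,
    "gastroenterology": 0.05,
}

#: diagnosis frequencies among eligible patients; pneumonia and urinary
#: tract infection dominate CDSS consultations
DIAGNOSIS_WEIGHTS = {
    "pneumonia": 0.28,
    "urinary_tract_infection": 0.26,
    "sepsis": 0.16,
    "fever_of_unknown_origin": 0.12,
    "secondary_peritonitis": 0.07,
    "meningitis": 0.06,
    "liver_abscess": 0.05,
}

#: most common first-choice drug per diagnosis (used to construct resistant
#: prior cultures); consistent with the example knowledge base
FIRST_CHOICE = {
    "pneumonia": "piperacillin-tazobactam",
    "urinary_tract_infection": "nitrofurantoin",
    "sepsis": "piperacillin-tazobactam",
    "fever_of_unknown_origin": "amoxicillin-clavulanate",
    "meningitis": "ceftriaxone",
    "secondary_peritonitis": "ceftriaxone",
    "liver_abscess": "amoxicillin-clavulanate",
}

_NON_CDSS_DIAGNOSES = ("cellulitis", "endocarditis", "osteomyelitis", "cholangitis")

_PANEL = (
    "piperacillin-tazobactam",
    "amoxicillin-clavulanate",
    "ceftriaxone",
    "ciprofloxacin",
    "gentamicin",
    "nitrofurantoin",
    "metronidazole",
)

T0 = datetime(2017, 1, 5, 8, 0)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=3349, ge=0)
    ward_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_WARD_WEIGHTS)
    )
    #: prevalence of CDSS-included diagnoses among non-prophylaxis patients
    eligible_prevalence: float = Field(default=0.403, ge=0, le=1)
    #: intended complete / partial / none adherence mixture (observed study
    #: mixture 91:23:55 of 169 by default)
    adherence_mixture: tuple[float, float, float] = (91 / 169, 23 / 169, 55 / 169)
    prophylaxis_only_rate: float = Field(default=0.15, ge=0, le=1)
    #: probability a prior culture resistant to the first-choice drug exists
    resistance_rate: float = Field(default=0.10, ge=0, le=1)
    #: share of female patients (study population value)
    female_rate: float = Field(default=0.444, ge=0, le=1)
    #: probability an eligible patient generates a real CDSS session
    session_rate: float = Field(default=0.125, ge=0, le=1)
    #: target fraction of all sessions that are test/try-out uses
    test_session_rate: float = Field(default=15 / 184, ge=0, lt=1)
    seed: int = 0

    @model_validator(mode="after")
    def _mixture_sums(self) -> "CohortConfig":
        if any(p < 0 for p in self.adherence_mixture):
            raise ValueError("adherence mixture probabilities must be non-negative")
        if abs(sum(self.adherence_mixture) - 1.0) > 1e-9:
            raise ValueError("adherence mixture must sum to 1")
        if not self.ward_weights or any(w < 0 for w in self.ward_weights.values()):
            raise ValueError("ward weights must be non-negative and non-empty")
        return self


class PatientTruth(BaseModel):
    model_config = ConfigDict(extra="forbid")

    eligible: bool
    prophylaxis_only: bool
    diagnosis: str | None = None
    intended_adherence: Literal["complete", "partial", "none"] | None = None
    partial_submode: Literal["drop_drug", "change_regimen"] | None = None
    intended_prophylaxis_rule: str | None = None


class SessionTruth(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    is_test: bool


class GroundTruth(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patients: dict[str, PatientTruth] = Field(default_factory=dict)
    sessions: dict[str, SessionTruth] = Field(default_factory=dict)
    config: CohortConfig


def generate_example_kb(path: str | None = None) -> KnowledgeBase:
    """Return the example knowledge base; optionally write it as YAML."""
    kb = example_kb()
    if path is not None:
        dump_kb(kb, path)
    return kb


def _choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _drive_session(kb, patient, diagnosis, at_time, rng) -> AdviceOutcome:
    """Run the advisor, answering manual questions uniformly at random."""
    session: Session = start_session(kb, patient, diagnosis, at_time)
    while session.status == "in_progress":
        node = session.node
        if isinstance(node, QuestionNode):
            answers = sorted(node.edges)
            submit_answer(session, answers[int(rng.integers(len(answers)))])
        else:
            acknowledge_gate(session)
    return generate_advice(session)


def _rx_from_advised(
    ad: AdvisedDrug, start: datetime, route=None, dose_factor=1.0
) -> Prescription:
    """A prescription realizing one advised drug (consult-marked doses get a
    nominal amount; adherence matching then compares drug and route only)."""
    dose = ad.dose
    return Prescription(
        atc=atc_for(ad.drug),
        drug=ad.drug,
        dose_amount=(dose.dose_amount if not dose.consult else 500) * dose_factor,
        dose_unit=dose.dose_unit if not dose.consult else "mg",
        route=route or ad.route,
        interval_hours=dose.interval_hours,
        start=start,
        stop=start + timedelta(days=5),
    )


def _flip(route: str) -> str:
    return "oral" if route == "iv" else "iv"


def _realize_adherence(
    advice: AdviceOutcome, at_time: datetime, rng: np.random.Generator,
    intended: str,
) -> tuple[list[Prescription], str | None]:
    """Prescriptions that make classify_adherence recover ``intended``."""
    start = at_time + timedelta(hours=2)
    drugs = advice.drugs
    if intended == "complete":
        return [_rx_from_advised(d, start) for d in drugs], None
    if intended == "none":
        decoy = "meropenem" if "meropenem" not in advice.drug_ids else "vancomycin"
        rx = Prescription(
            atc=atc_for(decoy), drug=decoy, dose_amount=1000, dose_unit="mg",
            route="iv", interval_hours=8, start=start,
            stop=start + timedelta(days=5),
        )
        return [rx], None
    # partial: drop one drug, or change the regimen of one drug
    if len(drugs) >= 2 and rng.random() < 0.5:
        return [_rx_from_advised(d, start) for d in drugs[:-1]], "drop_drug"
    modified = drugs[0]
    concrete = [d for d in drugs if not d.dose.consult]
    if concrete and rng.random() < 0.5:
        modified = concrete[0]
        rxs = [
            _rx_from_advised(d, start, dose_factor=2.0 if d is modified else 1.0)
            for d in drugs
        ]
    else:
        rxs = [
            _rx_from_advised(d, start, route=_flip(d.route) if d is modified else None)
            for d in drugs
        ]
    return rxs, "change_regimen"


def _background_rx(drug: str, start: datetime, rng: np.random.Generator) -> Prescription:
    days = int(rng.integers(3, 11))
    return Prescription(
        atc=atc_for(drug), drug=drug, dose_amount=1000, dose_unit="mg",
        route="iv", interval_hours=8, start=start,
        stop=start + timedelta(days=days),
    )


_PROPHYLAXIS_MODES = (
    "duration_lt_48h",
    "cotrimoxazole_480",
    "perioperative_cefazolin",
    "sdd",
    "copd",
    "pheneticillin_post_splenectomy",
)


def _prophylaxis_rx(mode: str, start: datetime) -> Prescription:
    if mode == "duration_lt_48h":
        return Prescription(atc=atc_for("ceftriaxone"), drug="ceftriaxone",
                            dose_amount=2, dose_unit="g", route="iv",
                            interval_hours=24, start=start,
                            stop=start + timedelta(hours=36))
    if mode == "cotrimoxazole_480":
        return Prescription(atc=atc_for("cotrimoxazole"), drug="cotrimoxazole",
                            dose_amount=480, dose_unit="mg", route="oral",
                            interval_hours=24, start=start,
                            stop=start + timedelta(days=10))
    if mode == "perioperative_cefazolin":
        return Prescription(atc=atc_for("cefazolin"), drug="cefazolin",
                            dose_amount=1000, dose_unit="mg", route="iv",
                            interval_hours=8, start=start,
                            stop=start + timedelta(days=3),
                            perioperative_context="pre", clear_indication=False)
    if mode in ("sdd", "copd"):
        return Prescription(atc=atc_for("cotrimoxazole"), drug="cotrimoxazole",
                            dose_amount=960, dose_unit="mg", route="oral",
                            interval_hours=24, start=start,
                            stop=start + timedelta(days=14), protocol_tag=mode)
    if mode == "pheneticillin_post_splenectomy":
        return Prescription(atc=atc_for("pheneticillin"), drug="pheneticillin",
                            dose_amount=250, dose_unit="mg", route="oral",
                            interval_hours=12, start=start,
                            stop=start + timedelta(days=30),
                            splenectomy_date=(start - timedelta(days=200)).date())
    raise ValueError(mode)


def _resistant_culture(
    diagnosis: str, at_time: datetime, rng: np.random.Generator
) -> CultureResult:
    first = FIRST_CHOICE[diagnosis]
    antibiogram = {d: "S" for d in _PANEL}
    antibiogram[first] = "R"
    return CultureResult(
        specimen=str(rng.choice(["urine", "blood", "sputum"])),
        collected_at=at_time - timedelta(days=int(rng.integers(20, 150))),
        organism="Escherichia coli",
        antibiogram=antibiogram,
    )


def generate_cohort(
    config: CohortConfig, kb: KnowledgeBase | None = None
) -> tuple[list[PatientRecord], list[SessionRecord], GroundTruth]:
    """Generate a synthetic cohort, its CDSS sessions, and ground truth.

    Each patient's draws come from an independent spawned stream of the
    run seed; identical configs therefore produce identical output.
    """
    kb = kb or example_kb()
    truth = GroundTruth(config=config)
    cohort: list[PatientRecord] = []
    sessions: list[SessionRecord] = []
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    # per-patient probability of a try-out session, chosen so the expected
    # test share of all sessions equals config.test_session_rate
    r = config.test_session_rate
    p_real = (
        (1 - config.prophylaxis_only_rate)
        * config.eligible_prevalence
        * config.session_rate
    )
    p_test = p_real * r / (1 - r)

    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pid = f"P{i:05d}"
        ward = _choice(rng, config.ward_weights)
        sex = "female" if rng.random() < config.female_rate else "male"
        admission_start = T0 + timedelta(
            days=int(rng.integers(0, 140)), hours=int(rng.integers(0, 10))
        )
        admission_end = admission_start + timedelta(days=int(rng.integers(2, 21)))
        years = int(rng.integers(18, 95))
        birth_date = (
            admission_start - timedelta(days=round(years * 365.25) + int(rng.integers(10, 300)))
        ).date()
        age = years
        pregnant = (
            sex == "female" and age < 50 and rng.random() < 0.05
        )
        allergies = (
            [Allergy(drug_class="penicillin", ige_mediated=True)]
            if rng.random() < 0.08
            else []
        )
        observations = [
            Observation(kind="egfr", value=float(rng.integers(15, 121)),
                        observed_at=admission_start + timedelta(hours=2)),
            Observation(kind="neutrophils", value=round(float(rng.uniform(0.2, 9.0)), 1),
                        observed_at=admission_start + timedelta(hours=2)),
        ]

        u = rng.random()
        prophylaxis_only = u < config.prophylaxis_only_rate
        eligible = not prophylaxis_only and rng.random() < config.eligible_prevalence

        prescriptions: list[Prescription] = []
        cultures: list[CultureResult] = []
        diagnosis: str | None = None
        intended: str | None = None
        submode: str | None = None
        prophylaxis_rule: str | None = None
        at_time = admission_start + timedelta(days=1, hours=int(rng.integers(0, 8)))

        if prophylaxis_only:
            prophylaxis_rule = _PROPHYLAXIS_MODES[
                int(rng.integers(len(_PROPHYLAXIS_MODES)))
            ]
            prescriptions.append(
                _prophylaxis_rx(prophylaxis_rule, admission_start + timedelta(hours=6))
            )
        elif eligible:
            diagnosis = _choice(rng, DIAGNOSIS_WEIGHTS)
            if rng.random() < config.resistance_rate:
                cultures.append(_resistant_culture(diagnosis, at_time, rng))
        else:
            diagnosis = str(rng.choice(_NON_CDSS_DIAGNOSES))
            prescriptions.append(
                _background_rx(
                    str(rng.choice(["flucloxacillin", "ceftriaxone", "doxycycline"])),
                    admission_start + timedelta(hours=6),
                    rng,
                )
            )

        patient = PatientRecord(
            patient_id=pid,
            birth_date=birth_date,
            sex=sex,
            ward=ward,
            admission_start=admission_start,
            admission_end=admission_end,
            weight_kg=round(float(rng.uniform(50, 110)), 1),
            height_cm=round(float(rng.uniform(150, 195)), 1),
            pregnant=pregnant,
            allergies=allergies,
            observations=observations,
            cultures=cultures,
            prescriptions=prescriptions,
            diagnoses=[diagnosis] if diagnosis else [],
        )

        has_real_session = eligible and rng.random() < config.session_rate
        if has_real_session:
            advice = _drive_session(kb, patient, diagnosis, at_time, rng)
            if advice.kind == "regimen":
                intended = ("complete", "partial", "none")[
                    int(rng.choice(3, p=list(config.adherence_mixture)))
                ]
                rxs, submode = _realize_adherence(advice, at_time, rng, intended)
                patient.prescriptions.extend(rxs)
            else:
                # consult advice: keep the patient therapeutic so the cohort
                # filter retains them
                patient.prescriptions.append(
                    _background_rx("ceftriaxone", at_time + timedelta(hours=3), rng)
                )
            sid = f"S-{pid}"
            sessions.append(SessionRecord(
                session_id=sid, patient_id=pid, diagnosis=diagnosis,
                at_time=at_time, is_test=False, advice=advice,
            ))
            truth.sessions[sid] = SessionTruth(patient_id=pid, is_test=False)
        elif eligible:
            # eligible, CDSS not used: ordinary guideline-agnostic therapy
            patient.prescriptions.append(
                _background_rx(FIRST_CHOICE[diagnosis],
                               admission_start + timedelta(hours=6), rng)
            )

        if rng.random() < p_test:
            test_diag = _choice(rng, DIAGNOSIS_WEIGHTS)
            advice = _drive_session(
                kb, patient, test_diag, at_time + timedelta(hours=1), rng
            )
            sid = f"T-{pid}"
            sessions.append(SessionRecord(
                session_id=sid, patient_id=pid, diagnosis=test_diag,
                at_time=at_time + timedelta(hours=1), is_test=True, advice=advice,
            ))
            truth.sessions[sid] = SessionTruth(patient_id=pid, is_test=True)

        truth.patients[pid] = PatientTruth(
            eligible=eligible,
            prophylaxis_only=prophylaxis_only,
            diagnosis=diagnosis,
            intended_adherence=intended,
            partial_submode=submode,
            intended_prophylaxis_rule=prophylaxis_rule,
        )
        cohort.append(patient)

    return cohort, sessions, truth
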