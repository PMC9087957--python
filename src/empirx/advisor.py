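"""Interactive advisor engine: pathway traversal, calculators, dose selection.

A :class:`Session` walks a diagnosis flowchart for one patient. Questions
bound to patient data are answered automatically (trail source ``auto``)
unless the value is missing or stale, in which case the question falls back
to manual input; a manual answer may later override an automatic one, and
the trail keeps both. The antibiogram gate is a hard stop: the clinician
must acknowledge the culture review before the traversal proceeds, and the
in-window cultures are attached to the session for display.

The terminal advice combines the pathway's regimen with two refinement
stages: deviation (substitute the first alternative regimen free of
documented resistance or matching drug-class allergy, else refer to the
infectious-disease specialist) and renal/weight/pregnancy-aware dose
selection from the per-drug dose tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Literal, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .knowledge_base import (
    AdviceNode,
    DoseRuleTable,
    GateNode,
    KnowledgeBase,
    QuestionNode,
    Regimen,
)
from .patient_data import (
    Allergy,
    CultureResult,
    PatientRecord,
    age_at,
    cultures_in_window,
    latest_valid_egfr,
)

NEUTROPENIA_THRESHOLD = 0.5  # 10^9/L
OBS_FRESH_DAYS = 7


class EngineError(RuntimeError):
    """Illegal engine operation for the current session state."""


class UnknownDiagnosisError(KeyError):
    def __init__(self, diagnosis: str, available: Sequence[str]):
        self.available = sorted(available)
        super().__init__(
            f"unknown diagnosis {diagnosis!r}; available: {', '.join(self.available)}"
        )


class IllegalAnswerError(ValueError):
    def __init__(self, node_id: str, answer: str, legal: Sequence[str]):
        self.legal = sorted(legal)
        super().__init__(
            f"answer {answer!r} not legal at {node_id}; expected one of {self.legal}"
        )


# ---------------------------------------------------------------------------
# clinical calculators


@dataclass(frozen=True)
class ClinicalMeasures:
    """Inputs to the CURB-65 pneumonia severity score."""

    confusion: bool
    urea: float  # mmol/L
    respiratory_rate: float  # /min
    systolic_bp: float  # mmHg
    diastolic_bp: float  # mmHg
    age: float  # years


def curb65(m: ClinicalMeasures) -> tuple[int, Literal["low", "moderate", "high"]]:
    """CURB-65 score and risk level.

    One point each for Confusion, Urea > 7 mmol/L, Respiratory rate >= 30,
    low Blood pressure (systolic < 90 or diastolic <= 60) and age >= 65.
    Risk: 0-1 low, 2 moderate, >=3 high.
    """
    for name in ("urea", "respiratory_rate", "systolic_bp", "diastolic_bp", "age"):
        if getattr(m, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    score = sum(
        [
            m.confusion,
            m.urea > 7,
            m.respiratory_rate >= 30,
            m.systolic_bp < 90 or m.diastolic_bp <= 60,
            m.age >= 65,
        ]
    )
    risk = "low" if score <= 1 else "moderate" if score == 2 else "high"
    return score, risk


def ideal_body_weight(sex: Literal["male", "female"], height_cm: float) -> float:
    """Devine ideal body weight (kg), floored at the base value below 152.4 cm."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    base = 50.0 if sex == "male" else 45.5
    return max(base, base + 0.9055 * (height_cm - 152.4))


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m²."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


# ---------------------------------------------------------------------------
# data bindings (auto-answer sources)


def _bind_pregnant(patient: PatientRecord, at_time: datetime) -> str | None:
    if patient.sex == "male":
        return "no"
    if patient.pregnant is None:
        return None  # always asked when unset and female
    return "yes" if patient.pregnant else "no"


def _bind_ige_allergy(patient: PatientRecord, at_time: datetime) -> str | None:
    return "yes" if any(a.ige_mediated for a in patient.allergies) else "no"


def _bind_neutropenic(patient: PatientRecord, at_time: datetime) -> str | None:
    fresh = [
        o for o in patient.observations
        if o.kind == "neutrophils"
        and o.observed_at <= at_time
        and at_time - o.observed_at < timedelta(days=OBS_FRESH_DAYS)
    ]
    latest = max(fresh, key=lambda o: o.observed_at, default=None)
    if latest is None:
        return None
    return "yes" if latest.value < NEUTROPENIA_THRESHOLD else "no"


def _bind_age_65_plus(patient: PatientRecord, at_time: datetime) -> str | None:
    return "yes" if age_at(patient.birth_date, at_time) >= 65 else "no"


BINDINGS: dict[str, Callable[[PatientRecord, datetime], str | None]] = {
    "pregnant": _bind_pregnant,
    "ige_allergy": _bind_ige_allergy,
    "neutropenic": _bind_neutropenic,
    "age_65_plus": _bind_age_65_plus,
}


# ---------------------------------------------------------------------------
# session


class TrailEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    node_id: str
    answer: str
    source: Literal["auto", "manual"]


@dataclass
class Session:
    kb: KnowledgeBase
    patient: PatientRecord
    diagnosis: str
    at_time: datetime
    current_node: str = ""
    answer_trail: list[TrailEntry] = field(default_factory=list)
    overridden: list[TrailEntry] = field(default_factory=list)
    gates_acknowledged: list[str] = field(default_factory=list)
    attached_cultures: list[CultureResult] = field(default_factory=list)
    status: Literal["in_progress", "complete"] = "in_progress"
    auto_answer: bool = True
    pinned: dict[str, str] = field(default_factory=dict)

    @property
    def pathway(self):
        return self.kb.diagnoses[self.diagnosis]

    @property
    def node(self):
        return self.pathway.nodes[self.current_node]


def start_session(
    kb: KnowledgeBase,
    patient: PatientRecord,
    diagnosis: str,
    at_time: datetime,
    auto_answer: bool = True,
) -> Session:
    """Open a session at the pathway root; bound questions answer themselves."""
    if diagnosis not in kb.diagnoses:
        raise UnknownDiagnosisError(diagnosis, list(kb.diagnoses))
    session = Session(
        kb=kb,
        patient=patient,
        diagnosis=diagnosis,
        at_time=at_time,
        current_node=kb.diagnoses[diagnosis].root,
        auto_answer=auto_answer,
    )
    _advance(session)
    return session


def _advance(session: Session) -> None:
    """Walk forward until a manual question, a gate, or an advice node."""
    while True:
        node = session.node
        if isinstance(node, AdviceNode):
            session.status = "complete"
            return
        if isinstance(node, GateNode):
            return  # must be acknowledged explicitly
        answer: str | None = None
        source: Literal["auto", "manual"] = "auto"
        if node.id in session.pinned:
            answer, source = session.pinned[node.id], "manual"
        elif session.auto_answer and node.data_binding in BINDINGS:
            answer = BINDINGS[node.data_binding](session.patient, session.at_time)
        if answer is None or answer not in node.edges:
            return  # manual input required
        session.answer_trail.append(
            TrailEntry(node_id=node.id, answer=answer, source=source)
        )
        session.current_node = node.edges[answer]


def submit_answer(session: Session, answer: str) -> Session:
    """Answer the current (manual) question and advance."""
    if session.status != "in_progress":
        raise EngineError("session already complete")
    node = session.node
    if not isinstance(node, QuestionNode):
        raise EngineError(f"current node {node.id} is not a question")
    if answer not in node.edges:
        raise IllegalAnswerError(node.id, answer, list(node.edges))
    session.answer_trail.append(
        TrailEntry(node_id=node.id, answer=answer, source="manual")
    )
    session.current_node = node.edges[answer]
    _advance(session)
    return session


def acknowledge_gate(session: Session) -> Session:
    """Acknowledge the antibiogram review; attaches in-window cultures."""
    node = session.node
    if not isinstance(node, GateNode):
        raise EngineError(f"current node {node.id} is not a gate")
    session.gates_acknowledged.append(node.id)
    session.attached_cultures = cultures_in_window(
        session.patient, session.at_time, node.window_days
    )
    session.current_node = node.next_node
    _advance(session)
    return session


def override_answer(session: Session, node_id: str, answer: str) -> Session:
    """Manually overwrite an earlier (possibly automatic) answer.

    The traversal rewinds to ``node_id`` and replays; superseded trail
    entries are kept in ``session.overridden``.
    """
    idx = next(
        (i for i, e in enumerate(session.answer_trail) if e.node_id == node_id), None
    )
    if idx is None:
        raise EngineError(f"node {node_id} was not answered in this session")
    node = session.pathway.nodes[node_id]
    assert isinstance(node, QuestionNode)
    if answer not in node.edges:
        raise IllegalAnswerError(node_id, answer, list(node.edges))
    session.overridden.extend(session.answer_trail[idx:])
    session.answer_trail = session.answer_trail[:idx]
    session.pinned[node_id] = answer
    session.current_node = node_id
    session.status = "in_progress"
    _advance(session)
    return session


# ---------------------------------------------------------------------------
# dose selection


class WeightUsed(BaseModel):
    model_config = ConfigDict(extra="forbid")

    basis: Literal["actual", "ideal"]
    kg: float


@dataclass(frozen=True)
class WeightContext:
    sex: Literal["male", "female"]
    height_cm: float | None = None
    weight_kg: float | None = None


class DoseDecision(BaseModel):
    """Resolved dose for one drug: a concrete regimen row or a consult marker."""

    model_config = ConfigDict(extra="forbid")

    drug: str
    dose_amount: float | None = None
    dose_unit: str | None = None
    interval_hours: int | None = None
    weight_used: WeightUsed | None = None
    consult: bool = False
    rationale: str = ""

    @model_validator(mode="after")
    def _one_of(self) -> "DoseDecision":
        has_dose = self.dose_amount is not None
        if self.consult == has_dose:
            raise ValueError("exactly one of dose row / consult marker")
        return self


def _consult(drug: str, why: str) -> DoseDecision:
    return DoseDecision(drug=drug, consult=True, rationale=why)


def select_dose(
    drug: str,
    kb: KnowledgeBase,
    egfr: float | None = None,
    weight_ctx: WeightContext | None = None,
    pregnant: bool = False,
) -> DoseDecision:
    """Resolve a drug's dose from its rule table.

    An absent eGFR with a renally banded table, a pregnancy-disallowed row,
    a consult band, or missing weight data all resolve to the consult
    marker rather than a guess.
    """
    table: DoseRuleTable | None = kb.dose_rules.get(drug)
    if table is None:
        raise KeyError(f"no dose rule table for drug {drug!r}")
    if egfr is None:
        if table.renal_dependent:
            return _consult(drug, "no valid eGFR for a renally adjusted drug")
        row = table.rows[0]
    else:
        row = next((r for r in table.rows if r.matches(egfr)), None)
        if row is None:
            return _consult(drug, f"no dose band matches eGFR {egfr}")
    if pregnant and not row.pregnancy_allowed:
        return _consult(drug, "row not allowed in pregnancy")
    if row.consult:
        return _consult(drug, f"consult band at eGFR {egfr}")

    amount, unit = row.dose_amount, row.dose_unit
    weight_used = None
    if row.weight_basis != "none":
        if row.weight_basis == "ideal":
            if weight_ctx is None or weight_ctx.height_cm is None:
                return _consult(drug, "ideal body weight requires height")
            kg = ideal_body_weight(weight_ctx.sex, weight_ctx.height_cm)
        else:
            if weight_ctx is None or weight_ctx.weight_kg is None:
                return _consult(drug, "actual body weight not recorded")
            kg = weight_ctx.weight_kg
        weight_used = WeightUsed(basis=row.weight_basis, kg=round(kg, 2))
        if unit and unit.endswith("/kg"):
            amount = round(amount * kg, 1)
            unit = unit[: -len("/kg")]
    return DoseDecision(
        drug=drug,
        dose_amount=amount,
        dose_unit=unit,
        interval_hours=row.interval_hours,
        weight_used=weight_used,
        rationale=f"eGFR band [{row.egfr_min}, {row.egfr_max if row.egfr_max is not None else 'inf'})",
    )


# ---------------------------------------------------------------------------
# deviation and final advice


class DeviationRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reason: Literal["resistance", "allergy"]
    from_drugs: list[str]
    to_drugs: list[str] | None = None  # None -> referred to consult


def _drug_conflicts(
    drug: str,
    cultures: Sequence[CultureResult],
    allergies: Sequence[Allergy],
    kb: KnowledgeBase,
    resistant_codes: frozenset[str],
) -> str | None:
    """Return 'resistance', 'allergy' or None for one drug."""
    if any(c.antibiogram.get(drug) in resistant_codes for c in cultures):
        return "resistance"
    table = kb.dose_rules.get(drug)
    if table is not None and any(a.drug_class == table.drug_class for a in allergies):
        return "allergy"
    return None


def apply_deviation(
    regimen: Regimen,
    cultures: Sequence[CultureResult],
    allergies: Sequence[Allergy],
    kb: KnowledgeBase,
    treat_intermediate_as_resistant: bool = False,
) -> tuple[Regimen | None, DeviationRecord | None]:
    """Deviate from the first-choice regimen when cultures or allergies block it.

    ``cultures`` must already be restricted to the review window. Returns the
    first alternative regimen whose drugs carry neither a documented R result
    nor a matching drug-class allergy; ``(None, record)`` means refer to the
    infectious-disease specialist. Intermediate (I) results do not trigger
    deviation unless ``treat_intermediate_as_resistant`` is set.
    """
    codes = frozenset({"R", "I"} if treat_intermediate_as_resistant else {"R"})
    conflicts = [
        _drug_conflicts(d, cultures, allergies, kb, codes) for d in regimen.drug_ids
    ]
    if not any(conflicts):
        return regimen, None
    reason = "resistance" if "resistance" in conflicts else "allergy"
    for alt in regimen.alternatives:
        if not any(
            _drug_conflicts(d, cultures, allergies, kb, codes) for d in alt.drug_ids
        ):
            return alt, DeviationRecord(
                reason=reason, from_drugs=regimen.drug_ids, to_drugs=alt.drug_ids
            )
    return None, DeviationRecord(
        reason=reason, from_drugs=regimen.drug_ids, to_drugs=None
    )


class AdvisedDrug(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug: str
    route: Literal["iv", "oral"]
    dose: DoseDecision


class AdviceOutcome(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["regimen", "consult_id"]
    drugs: list[AdvisedDrug] = []
    duration_days: int | list[int] | None = None
    deviation: DeviationRecord | None = None
    answer_trail: list[TrailEntry] = []

    @model_validator(mode="after")
    def _consistent(self) -> "AdviceOutcome":
        if self.kind == "regimen" and not self.drugs:
            raise ValueError("regimen advice needs at least one dosed drug")
        if self.kind == "consult_id" and self.drugs:
            raise ValueError("consult advice carries no regimen")
        return self

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug for d in self.drugs]


def generate_advice(session: Session) -> AdviceOutcome:
    """Compose the final advice at the session's terminal advice node."""
    if session.status != "complete":
        raise EngineError("session is not complete")
    node = session.node
    assert isinstance(node, AdviceNode)
    trail = list(session.answer_trail)
    if node.consult:
        return AdviceOutcome(kind="consult_id", answer_trail=trail)

    # gate window governs which cultures may drive deviation
    windows = [
        n.window_days
        for nid in session.gates_acknowledged
        if isinstance((n := session.pathway.nodes[nid]), GateNode)
    ]
    cultures = cultures_in_window(
        session.patient, session.at_time, max(windows) if windows else 183
    )
    regimen, deviation = apply_deviation(
        node.regimen, cultures, session.patient.allergies, session.kb
    )
    if regimen is None:
        return AdviceOutcome(kind="consult_id", deviation=deviation, answer_trail=trail)

    egfr_obs = latest_valid_egfr(session.patient, session.at_time)
    weight_ctx = WeightContext(
        sex=session.patient.sex,
        height_cm=session.patient.height_cm,
        weight_kg=session.patient.weight_kg,
    )
    advised = [
        AdvisedDrug(
            drug=order.drug,
            route=order.route,
            dose=select_dose(
                order.drug,
                session.kb,
                egfr=None if egfr_obs is None else egfr_obs.value,
                weight_ctx=weight_ctx,
                pregnant=bool(session.patient.pregnant),
            ),
        )
        for order in regimen.drugs
    ]
    return AdviceOutcome(
        kind="regimen",
        drugs=advised,
        duration_days=regimen.duration_days,
        deviation=deviation,
        answer_trail=trail,
    )
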