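"""Declarative guideline knowledge base: diagnosis flowcharts and dose rules.

A knowledge base holds one rooted decision flowchart per working diagnosis
(questions, an obligatory antibiogram-review gate, terminal advice nodes)
plus per-drug dose rule tables banded on renal function (eGFR). The file
format is YAML (JSON is accepted, being a YAML subset); see
``docs/kb_schema.md`` for the schema.

Loading (:func:`load_kb`) enforces referential integrity only; all clinical
well-formedness checks (acyclicity, reachability, termination in an advice
node, answer-edge completeness, dose-table presence and eGFR-band coverage)
are performed by :func:`validate_kb`, which reports violations as data so
that a broken chart can be linted rather than merely rejected.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Annotated, Literal, Union

import networkx as nx
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class KBParseError(ValueError):
    """Raised when a knowledge-base file cannot be parsed or cross-referenced."""


class DrugOrder(BaseModel):
    """One drug within a regimen: what to give and by which route."""

    model_config = ConfigDict(extra="forbid")

    drug: str
    route: Literal["iv", "oral"]


class Regimen(BaseModel):
    """An antibiotic regimen with ranked alternatives for deviation.

    Alternatives are ordered: the engine substitutes the first alternative
    free of resistance/allergy conflicts when the first choice is blocked.
    """

    model_config = ConfigDict(extra="forbid")

    drugs: list[DrugOrder] = Field(min_length=1)
    duration_days: int | list[int] | None = None
    alternatives: list["Regimen"] = Field(default_factory=list)
    notes: str = ""

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug for d in self.drugs]

    def all_drug_ids(self) -> set[str]:
        """Drug ids of this regimen and, recursively, its alternatives."""
        out = set(self.drug_ids)
        for alt in self.alternatives:
            out |= alt.all_drug_ids()
        return out


class QuestionNode(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["question"]
    id: str = ""
    prompt: str
    #: names a patient-record binding that can auto-answer this question
    data_binding: str | None = None
    #: answer value -> next node id
    edges: dict[str, str]
    #: declared legal answers; edges must cover exactly this set
    answers: list[str] | None = None

    def declared_answers(self) -> list[str]:
        return self.answers if self.answers is not None else sorted(self.edges)


class GateNode(BaseModel):
    """A mandatory stop: the clinician must review prior culture results."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    kind: Literal["gate"]
    id: str = ""
    gate_kind: Literal["antibiogram_review"] = "antibiogram_review"
    window_days: int = 183
    next_node: str = Field(alias="next")


class AdviceNode(BaseModel):
    """Terminal node: a concrete regimen or a referral to the ID specialist."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["advice"]
    id: str = ""
    regimen: Regimen | None = None
    consult: bool = False

    @model_validator(mode="after")
    def _one_of(self) -> "AdviceNode":
        if (self.regimen is None) == (not self.consult):
            raise ValueError("advice node needs exactly one of regimen / consult")
        return self


DecisionNode = Annotated[
    Union[QuestionNode, GateNode, AdviceNode], Field(discriminator="kind")
]


class DiagnosisPathway(BaseModel):
    model_config = ConfigDict(extra="forbid")

    diagnosis: str
    root: str
    nodes: dict[str, QuestionNode | GateNode | AdviceNode]

    def successors(self, node_id: str) -> list[str]:
        node = self.nodes[node_id]
        if isinstance(node, QuestionNode):
            return list(node.edges.values())
        if isinstance(node, GateNode):
            return [node.next_node]
        return []


class DoseRuleRow(BaseModel):
    """One eGFR band of a dose table.

    Bands are half-open ``[egfr_min, egfr_max)`` in mL/min/1.73 m²;
    ``egfr_max: null`` means unbounded above. A band may carry
    ``consult: true`` instead of a dose (renal contraindication).
    Per-kilogram dosing uses a unit ending in ``/kg`` together with
    ``weight_basis`` (``ideal`` resolves through the Devine formula).
    """

    model_config = ConfigDict(extra="forbid")

    egfr_min: float = 0.0
    egfr_max: float | None = None
    weight_basis: Literal["actual", "ideal", "none"] = "none"
    pregnancy_allowed: bool = True
    dose_amount: float | None = None
    dose_unit: str | None = None
    interval_hours: int | None = None
    consult: bool = False

    @model_validator(mode="after")
    def _dose_or_consult(self) -> "DoseRuleRow":
        has_dose = (
            self.dose_amount is not None
            and self.dose_unit is not None
            and self.interval_hours is not None
        )
        if self.consult == has_dose:
            raise ValueError("dose row needs either a full dose or consult: true")
        return self

    def matches(self, egfr: float) -> bool:
        return self.egfr_min <= egfr and (self.egfr_max is None or egfr < self.egfr_max)


class DoseRuleTable(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug: str
    drug_class: str
    rows: list[DoseRuleRow] = Field(min_length=1)
    fallback: Literal["consult"] = "consult"

    @property
    def renal_dependent(self) -> bool:
        """True when dosing differs by renal function (an eGFR is required)."""
        return len(self.rows) > 1 or self.rows[0].egfr_min > 0 or self.rows[0].egfr_max is not None


class KnowledgeBase(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    version: str = "1"
    diagnoses: dict[str, DiagnosisPathway]
    dose_rules: dict[str, DoseRuleTable]


class Violation(BaseModel):
    rule: str
    where: str
    message: str


class ValidationReport(BaseModel):
    violations: list[Violation] = Field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # human-readable lint output
        if self.is_valid:
            return "OK: knowledge base is valid"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.rule}] {v.where}: {v.message}" for v in self.violations]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# loading


def _inject_ids(raw: dict) -> dict:
    raw = json.loads(json.dumps(raw))  # deep copy, also normalizes tuples
    for name, path in raw.get("diagnoses", {}).items():
        path.setdefault("diagnosis", name)
        for node_id, node in path.get("nodes", {}).items():
            if isinstance(node, dict):
                node.setdefault("id", node_id)
    for drug, table in raw.get("dose_rules", {}).items():
        if isinstance(table, dict):
            table.setdefault("drug", drug)
    return raw


def load_kb(source: str | Path | dict) -> KnowledgeBase:
    """Load and cross-reference a knowledge base from YAML/JSON or a dict.

    Raises :class:`KBParseError` naming the offending location on schema
    violations or unresolved node references. The returned model is frozen.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise KBParseError("knowledge base file must contain a mapping at top level")
    try:
        kb = KnowledgeBase.model_validate(_inject_ids(raw))
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise KBParseError(f"schema violation at {loc}: {first['msg']}") from err
    for name, pathway in kb.diagnoses.items():
        if pathway.root not in pathway.nodes:
            raise KBParseError(f"{name}: root node {pathway.root!r} not defined")
        for node_id, node in pathway.nodes.items():
            for target in pathway.successors(node_id):
                if target not in pathway.nodes:
                    raise KBParseError(
                        f"{name}.{node_id}: edge targets missing node {target!r}"
                    )
    return kb


def dump_kb(kb: KnowledgeBase, path: str | Path | None = None) -> str:
    """Serialize a knowledge base to canonical YAML; optionally write it."""
    raw = kb.model_dump(mode="json", by_alias=True, exclude_defaults=False)
    text = yaml.safe_dump(raw, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# validation


def _pathway_graph(pathway: DiagnosisPathway) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(pathway.nodes)
    for node_id in pathway.nodes:
        for target in pathway.successors(node_id):
            if target in pathway.nodes:
                g.add_edge(node_id, target)
    return g


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Lint a knowledge base; violations are returned as data, not raised.

    Checks per pathway: root resolution, dangling edges, acyclicity,
    reachability from the root, termination of every path in an advice
    node, answer-edge completeness on questions; per dose table: presence
    for every advised drug (alternatives included) and non-overlapping
    eGFR bands jointly covering [0, inf).
    """
    out: list[Violation] = []
    for name, pathway in kb.diagnoses.items():
        if pathway.root not in pathway.nodes:
            out.append(Violation(rule="root_missing", where=name,
                                 message=f"root {pathway.root!r} is not a node"))
            continue
        for node_id, node in pathway.nodes.items():
            for target in pathway.successors(node_id):
                if target not in pathway.nodes:
                    out.append(Violation(rule="dangling_edge", where=f"{name}.{node_id}",
                                         message=f"edge targets missing node {target!r}"))
            if isinstance(node, QuestionNode):
                declared = set(node.declared_answers())
                got = set(node.edges)
                if len(declared) < 2:
                    out.append(Violation(rule="question_min_edges", where=f"{name}.{node_id}",
                                         message="question needs >= 2 distinct answers"))
                if got != declared:
                    missing = sorted(declared - got)
                    extra = sorted(got - declared)
                    out.append(Violation(
                        rule="answer_completeness", where=f"{name}.{node_id}",
                        message=f"edges do not cover declared answers "
                                f"(missing {missing}, undeclared {extra})"))
        g = _pathway_graph(pathway)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            out.append(Violation(rule="cycle", where=name,
                                 message=f"cycle through {[e[0] for e in cycle]}"))
        else:
            reachable = nx.descendants(g, pathway.root) | {pathway.root}
            for node_id in pathway.nodes:
                if node_id not in reachable:
                    out.append(Violation(rule="unreachable", where=f"{name}.{node_id}",
                                         message="node not reachable from root"))
        for node_id, node in pathway.nodes.items():
            terminal = not pathway.successors(node_id) or all(
                t not in pathway.nodes for t in pathway.successors(node_id)
            )
            if terminal and not isinstance(node, AdviceNode):
                out.append(Violation(rule="no_advice_terminal", where=f"{name}.{node_id}",
                                     message="path ends without a generated advice"))
            if isinstance(node, AdviceNode) and node.regimen is not None:
                for drug in sorted(node.regimen.all_drug_ids()):
                    if drug not in kb.dose_rules:
                        out.append(Violation(rule="missing_dose_table",
                                             where=f"{name}.{node_id}",
                                             message=f"no dose rule table for {drug!r}"))
    for drug, table in kb.dose_rules.items():
        out.extend(_check_band_coverage(drug, table))
    return ValidationReport(violations=out)


def _check_band_coverage(drug: str, table: DoseRuleTable) -> list[Violation]:
    out: list[Violation] = []
    rows = sorted(table.rows, key=lambda r: r.egfr_min)
    cursor = 0.0
    for row in rows:
        hi = math.inf if row.egfr_max is None else row.egfr_max
        if row.egfr_min >= hi:
            out.append(Violation(rule="band_empty", where=drug,
                                 message=f"empty band [{row.egfr_min}, {row.egfr_max})"))
            continue
        if row.egfr_min > cursor:
            out.append(Violation(rule="band_gap", where=drug,
                                 message=f"eGFR gap [{cursor}, {row.egfr_min}) uncovered"))
        elif row.egfr_min < cursor:
            out.append(Violation(rule="band_overlap", where=drug,
                                 message=f"band starting at {row.egfr_min} overlaps previous"))
        cursor = max(cursor, hi)
    if cursor != math.inf:
        out.append(Violation(rule="band_gap", where=drug,
                             message=f"eGFR range [{cursor}, inf) uncovered"))
    return out


# ---------------------------------------------------------------------------
# path enumeration (oracle for engine-equivalence tests)


class PathRecord(BaseModel):
    """One root-to-advice traversal: the question answers plus the terminal."""

    answers: list[tuple[str, str]]  # (question node id, answer value)
    terminal: str  # advice node id


def enumerate_paths(kb: KnowledgeBase, diagnosis: str) -> list[PathRecord]:
    """Exhaustively enumerate all root-to-advice paths of a pathway.

    Gates are traversed silently (they carry no answer); the count of
    returned paths equals the number of distinct answer combinations.
    Requires an acyclic, terminating pathway (run :func:`validate_kb` first).
    """
    if diagnosis not in kb.diagnoses:
        raise KeyError(f"unknown diagnosis {diagnosis!r}; "
                       f"available: {sorted(kb.diagnoses)}")
    pathway = kb.diagnoses[diagnosis]
    out: list[PathRecord] = []

    def walk(node_id: str, answers: list[tuple[str, str]]) -> None:
        node = pathway.nodes[node_id]
        if isinstance(node, AdviceNode):
            out.append(PathRecord(answers=list(answers), terminal=node_id))
        elif isinstance(node, GateNode):
            walk(node.next_node, answers)
        else:
            for answer in sorted(node.edges):
                walk(node.edges[answer], answers + [(node_id, answer)])

    walk(pathway.root, [])
    return out
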