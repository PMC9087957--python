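"""Patient/cohort data model, EHR-extract readers, and data-binding rules.

The canonical cohort exchange format is JSON lines (one patient object per
line); a CSV bundle (patients.csv, observations.csv, cultures.csv,
prescriptions.csv in one directory) is accepted as an alternative. See
``docs/cohort_schema.md``.

Two freshness rules govern what patient data the advisor may use
automatically: an eGFR value is only presented if determined strictly less
than one week before the consultation, and only culture results from the
previous six months (183 days) are shown.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

EGFR_FRESH_DAYS = 7
CULTURE_WINDOW_DAYS = 183


class CohortReadError(ValueError):
    """Raised for malformed cohort extract rows, naming row and field."""


class Allergy(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug_class: str
    ige_mediated: bool = False


class Observation(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["egfr", "neutrophils"]
    value: float = Field(ge=0)  # mL/min/1.73 m² or 10^9/L
    observed_at: datetime


class CultureResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    specimen: str
    collected_at: datetime
    organism: str | None = None
    #: drug id -> S (susceptible) / I (intermediate) / R (resistant)
    antibiogram: dict[str, Literal["S", "I", "R"]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _antibiogram_present(self) -> "CultureResult":
        if self.organism and not self.antibiogram:
            raise ValueError("antibiogram required when an organism was cultured")
        return self


class Prescription(BaseModel):
    model_config = ConfigDict(extra="forbid")

    atc: str
    drug: str
    dose_amount: float
    dose_unit: str
    route: Literal["iv", "oral"]
    start: datetime
    stop: datetime | None = None
    interval_hours: int | None = None
    perioperative_context: Literal["pre", "intra", "post"] | None = None
    #: clear therapeutic indication (manual assessment for perioperative cefazolin)
    clear_indication: bool | None = None
    protocol_tag: Literal["sdd", "neutropenia", "copd", "post_splenectomy"] | None = None
    splenectomy_date: date | None = None

    @model_validator(mode="after")
    def _stop_after_start(self) -> "Prescription":
        if self.stop is not None and self.stop < self.start:
            raise ValueError("stop precedes start")
        return self


class PatientRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    birth_date: date
    sex: Literal["male", "female"]
    ward: str
    admission_start: datetime
    admission_end: datetime
    weight_kg: float | None = None
    height_cm: float | None = None
    pregnant: bool | None = None
    allergies: list[Allergy] = Field(default_factory=list)
    observations: list[Observation] = Field(default_factory=list)
    cultures: list[CultureResult] = Field(default_factory=list)
    prescriptions: list[Prescription] = Field(default_factory=list)
    #: working-diagnosis labels; used by the stewardship evaluation only
    diagnoses: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _admission_ordered(self) -> "PatientRecord":
        if self.admission_end < self.admission_start:
            raise ValueError("admission_end precedes admission_start")
        return self


def age_at(birth_date: date, when: datetime | date) -> int:
    """Completed years of age at a given moment."""
    if isinstance(when, datetime):
        when = when.date()
    years = when.year - birth_date.year
    if (when.month, when.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def is_systemic_antibacterial(atc: str) -> bool:
    """True iff the ATC code denotes an antibacterial for systemic use (J01)."""
    if not atc:
        raise ValueError("empty ATC code")
    return atc.startswith("J01")


def latest_valid_egfr(patient: PatientRecord, at_time: datetime) -> Observation | None:
    """Most recent eGFR determined strictly less than 7 days before ``at_time``.

    Returns ``None`` when no fresh value exists (the advisor then requires
    manual input). Values observed after ``at_time`` are never used.
    """
    fresh = [
        o for o in patient.observations
        if o.kind == "egfr"
        and o.observed_at <= at_time
        and at_time - o.observed_at < timedelta(days=EGFR_FRESH_DAYS)
    ]
    return max(fresh, key=lambda o: o.observed_at, default=None)


def cultures_in_window(
    patient: PatientRecord, at_time: datetime, window_days: int = CULTURE_WINDOW_DAYS
) -> list[CultureResult]:
    """Culture results from the preceding ``window_days``, newest first."""
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    lo = at_time - timedelta(days=window_days)
    hits = [c for c in patient.cultures if lo <= c.collected_at <= at_time]
    return sorted(hits, key=lambda c: c.collected_at, reverse=True)


# ---------------------------------------------------------------------------
# extract I/O


def read_cohort(source: str | Path) -> list[PatientRecord]:
    """Read a cohort extract: a ``.jsonl`` file or a CSV-bundle directory."""
    path = Path(source)
    if path.is_dir():
        return _read_csv_bundle(path)
    records: list[PatientRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(PatientRecord.model_validate_json(line))
            except ValidationError as err:
                first = err.errors()[0]
                field = ".".join(str(p) for p in first["loc"])
                raise CohortReadError(
                    f"{path.name} line {lineno}, field {field or '<record>'}: "
                    f"{first['msg']}"
                ) from err
    return records


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort as canonical JSON lines."""
    with Path(path).open("w") as fh:
        for patient in cohort:
            fh.write(patient.model_dump_json(exclude_none=True) + "\n")


def _clean(row: dict) -> dict:
    return {
        k: v
        for k, v in row.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v)) and v != ""
    }


def _read_csv_bundle(directory: Path) -> list[PatientRecord]:
    patients = pd.read_csv(directory / "patients.csv", dtype={"patient_id": str})
    by_id: dict[str, dict] = {}
    for _, row in patients.iterrows():
        rec = _clean(row.to_dict())
        if "allergies" in rec:
            rec["allergies"] = [
                {"drug_class": part.split("|")[0], "ige_mediated": part.split("|")[1] == "1"}
                for part in str(rec["allergies"]).split(";")
            ]
        if "diagnoses" in rec:
            rec["diagnoses"] = str(rec["diagnoses"]).split(";")
        rec.setdefault("observations", [])
        rec.setdefault("cultures", [])
        rec.setdefault("prescriptions", [])
        by_id[rec["patient_id"]] = rec

    def attach(filename: str, key: str, transform=None):
        file = directory / filename
        if not file.exists():
            return
        for _, row in pd.read_csv(file, dtype={"patient_id": str}).iterrows():
            item = _clean(row.to_dict())
            pid = item.pop("patient_id")
            if transform:
                item = transform(item)
            if pid not in by_id:
                raise CohortReadError(f"{filename}: unknown patient_id {pid!r}")
            by_id[pid][key].append(item)

    def parse_antibiogram(item: dict) -> dict:
        if "antibiogram" in item:
            item["antibiogram"] = dict(
                pair.split(":") for pair in str(item["antibiogram"]).split(";")
            )
        return item

    attach("observations.csv", "observations")
    attach("cultures.csv", "cultures", parse_antibiogram)
    attach("prescriptions.csv", "prescriptions")

    records = []
    for pid, rec in by_id.items():
        try:
            records.append(PatientRecord.model_validate(rec))
        except ValidationError as err:
            first = err.errors()[0]
            field = ".".join(str(p) for p in first["loc"])
            raise CohortReadError(
                f"patient {pid}, field {field or '<record>'}: {first['msg']}"
            ) from err
    return records
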