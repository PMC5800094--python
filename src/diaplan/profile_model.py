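"""Patient profiles: typed records, document ingestion, and derived classifiers.

A *patient profile* is one time-stamped snapshot of everything the planner may
look at: demographics, lab results, clinical records (symptoms, diseases,
current medications), and a flag for prior treatment plans.  Profiles are loaded
from JSON documents, validated against physiological bounds and the knowledge
base vocabulary, and handed to the rule engine, which is the only component
allowed to populate the ``derived`` fact set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Any, Optional

from .errors import MalformedProfileError, UnitError, UnknownCodeError

SEXES = frozenset({"male", "female"})
SOCIAL_STATES = frozenset({"poor", "intermediate", "rich"})
ACTIVITY_LEVELS = frozenset(
    {"sedentary", "light", "moderate", "very_active", "extra_active"}
)
RECORD_KINDS = frozenset({"symptom", "disease", "medication"})

# tests whose unit contract is enforced at load; other tests are extensible
PERCENT_TESTS = frozenset({"hba1c"})
GLUCOSE_TESTS = frozenset(
    {"fasting_plasma_glucose", "random_plasma_glucose", "plasma_glucose"}
)

MAX_AGE_YEARS = 130
MAX_HEIGHT_CM = 272.0
MAX_WEIGHT_KG = 650.0

DEFAULT_ADULT_AGE = 45  # strict ">" threshold; configurable per call


@dataclass
class Demographics:
    age: int
    sex: str
    height_cm: float
    weight_kg: float
    social_state: str
    activity_level: str
    language: str = "english"
    education_level: str = "unspecified"

    def validate(self) -> None:
        if not isinstance(self.age, int) or not 0 <= self.age <= MAX_AGE_YEARS:
            raise MalformedProfileError(f"age out of bounds: {self.age!r}")
        if self.sex not in SEXES:
            raise MalformedProfileError(f"sex must be one of {sorted(SEXES)}")
        if not 0 < float(self.height_cm) <= MAX_HEIGHT_CM:
            raise MalformedProfileError(f"height out of bounds: {self.height_cm!r}")
        if not 0 < float(self.weight_kg) <= MAX_WEIGHT_KG:
            raise MalformedProfileError(f"weight out of bounds: {self.weight_kg!r}")
        if self.social_state not in SOCIAL_STATES:
            raise MalformedProfileError(
                f"social_state must be one of {sorted(SOCIAL_STATES)}"
            )
        if self.activity_level not in ACTIVITY_LEVELS:
            raise MalformedProfileError(
                f"activity_level must be one of {sorted(ACTIVITY_LEVELS)}"
            )


@dataclass
class LabResult:
    test: str
    value: float
    unit: str
    date: Date

    def validate(self) -> None:
        if self.test in PERCENT_TESTS and self.unit != "%":
            raise UnitError(f"{self.test} must be reported in %, got {self.unit!r}")
        if self.test in GLUCOSE_TESTS and self.unit != "mg/dL":
            raise UnitError(
                f"{self.test} must be reported in mg/dL, got {self.unit!r}"
            )


@dataclass
class ClinicalRecord:
    kind: str  # symptom | disease | medication
    code: str
    severity: Optional[str] = None
    duration_days: Optional[int] = None
    is_diabetes_symptom: bool = False

    def validate(self) -> None:
        if self.kind not in RECORD_KINDS:
            raise MalformedProfileError(
                f"record kind must be one of {sorted(RECORD_KINDS)}"
            )


@dataclass
class PatientProfile:
    profile_id: str
    patient_id: str
    date: Date
    demographics: Demographics
    labs: list[LabResult] = field(default_factory=list)
    records: list[ClinicalRecord] = field(default_factory=list)
    has_previous_treatment_plan: bool = False
    # write-only by the rule engine; always empty after load
    derived: set[str] = field(default_factory=set)

    def records_of(self, kind: str) -> list[ClinicalRecord]:
        return [r for r in self.records if r.kind == kind]

    @property
    def diseases(self) -> list[str]:
        return [r.code for r in self.records_of("disease")]

    @property
    def medications(self) -> list[str]:
        return [r.code for r in self.records_of("medication")]

    @property
    def symptoms(self) -> list[str]:
        return [r.code for r in self.records_of("symptom")]

    def latest_lab(self, test: str) -> Optional[LabResult]:
        hits = [l for l in self.labs if l.test == test]
        return max(hits, key=lambda l: l.date) if hits else None


@dataclass
class Patient:
    patient_id: str
    profiles: list[PatientProfile] = field(default_factory=list)
    plans: list = field(default_factory=list)  # list[TreatmentPlan]

    def validate(self) -> None:
        if not self.profiles:
            raise MalformedProfileError(
                f"patient {self.patient_id} must have at least one profile"
            )
        dates = [p.date for p in self.profiles]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise MalformedProfileError(
                f"patient {self.patient_id}: profile dates must strictly increase"
            )

    @property
    def latest_profile(self) -> PatientProfile:
        return self.profiles[-1]

    @property
    def active_plan(self):
        for plan in reversed(self.plans):
            if plan.status == "active":
                return plan
        return None


# ---------------------------------------------------------------------------
# document ingestion


def _require(doc: dict, key: str, where: str) -> Any:
    if key not in doc:
        raise MalformedProfileError(f"missing required key {key!r} in {where}")
    return doc[key]


def _parse_date(raw: Any, where: str) -> Date:
    try:
        return Date.fromisoformat(str(raw))
    except ValueError as exc:
        raise MalformedProfileError(f"bad ISO date {raw!r} in {where}") from exc


def load_profile(document: Any, kb: Any = None) -> PatientProfile:
    """Load and validate one profile document.

    ``document`` may be a dict, a JSON string, or a path to a JSON file.
    When ``kb`` is given (a :class:`~diaplan.knowledge_base.KnowledgeBase`),
    record codes are resolved against its vocabulary and symptoms are flagged
    from it; unknown codes raise :class:`UnknownCodeError`.
    """
    if isinstance(document, (str, Path)) and not str(document).lstrip().startswith("{"):
        document = json.loads(Path(document).read_text())
    elif isinstance(document, str):
        document = json.loads(document)
    if not isinstance(document, dict):
        raise MalformedProfileError("profile document must be a JSON object")

    patient_id = str(_require(document, "patient_id", "profile"))
    prof_date = _parse_date(_require(document, "date", "profile"), "profile")
    profile_id = str(document.get("profile_id", f"{patient_id}:{prof_date}"))

    demo_doc = _require(document, "demographics", "profile")
    if not isinstance(demo_doc, dict):
        raise MalformedProfileError("demographics must be an object")
    for key in ("age", "sex", "height_cm", "weight_kg", "social_state",
                "activity_level"):
        _require(demo_doc, key, "demographics")
    demographics = Demographics(
        age=int(demo_doc["age"]),
        sex=str(demo_doc["sex"]),
        height_cm=float(demo_doc["height_cm"]),
        weight_kg=float(demo_doc["weight_kg"]),
        social_state=str(demo_doc["social_state"]),
        activity_level=str(demo_doc["activity_level"]),
        language=str(demo_doc.get("language", "english")),
        education_level=str(demo_doc.get("education_level", "unspecified")),
    )
    demographics.validate()

    labs = []
    for i, lab_doc in enumerate(_require(document, "labs", "profile")):
        lab = LabResult(
            test=str(_require(lab_doc, "test", f"labs[{i}]")),
            value=float(_require(lab_doc, "value", f"labs[{i}]")),
            unit=str(_require(lab_doc, "unit", f"labs[{i}]")),
            date=_parse_date(_require(lab_doc, "date", f"labs[{i}]"), f"labs[{i}]"),
        )
        lab.validate()
        labs.append(lab)

    records = []
    for i, rec_doc in enumerate(_require(document, "records", "profile")):
        rec = ClinicalRecord(
            kind=str(_require(rec_doc, "kind", f"records[{i}]")),
            code=str(_require(rec_doc, "code", f"records[{i}]")),
            severity=rec_doc.get("severity"),
            duration_days=rec_doc.get("duration_days"),
        )
        rec.validate()
        records.append(rec)

    if kb is not None:
        for rec in records:
            kb.resolve_record(rec)  # raises UnknownCodeError; flags symptoms

    flag = _require(document, "has_previous_treatment_plan", "profile")
    if not isinstance(flag, bool):
        raise MalformedProfileError("has_previous_treatment_plan must be boolean")

    return PatientProfile(
        profile_id=profile_id,
        patient_id=patient_id,
        date=prof_date,
        demographics=demographics,
        labs=labs,
        records=records,
        has_previous_treatment_plan=flag,
    )


def write_profile(profile: PatientProfile) -> dict:
    """Serialize a profile back to its document form (inverse of load)."""
    return {
        "profile_id": profile.profile_id,
        "patient_id": profile.patient_id,
        "date": profile.date.isoformat(),
        "demographics": {
            "age": profile.demographics.age,
            "sex": profile.demographics.sex,
            "height_cm": profile.demographics.height_cm,
            "weight_kg": profile.demographics.weight_kg,
            "social_state": profile.demographics.social_state,
            "activity_level": profile.demographics.activity_level,
            "language": profile.demographics.language,
            "education_level": profile.demographics.education_level,
        },
        "labs": [
            {
                "test": l.test,
                "value": l.value,
                "unit": l.unit,
                "date": l.date.isoformat(),
            }
            for l in profile.labs
        ],
        "records": [
            {
                "kind": r.kind,
                "code": r.code,
                **({"severity": r.severity} if r.severity is not None else {}),
                **(
                    {"duration_days": r.duration_days}
                    if r.duration_days is not None
                    else {}
                ),
            }
            for r in profile.records
        ],
        "has_previous_treatment_plan": profile.has_previous_treatment_plan,
    }


def load_cohort(source: Any, kb: Any = None) -> list[Patient]:
    """Load a cohort from NDJSON (one profile per line) or a directory of
    profile files, grouping profiles by patient_id in date order."""
    docs: list[dict] = []
    path = Path(source)
    if path.is_dir():
        for child in sorted(path.glob("*.json")):
            docs.append(json.loads(child.read_text()))
    else:
        for line in path.read_text().splitlines():
            if line.strip():
                docs.append(json.loads(line))
    by_patient: dict[str, list[PatientProfile]] = {}
    for doc in docs:
        prof = load_profile(doc, kb)
        by_patient.setdefault(prof.patient_id, []).append(prof)
    patients = []
    for pid, profs in by_patient.items():
        profs.sort(key=lambda p: p.date)
        patient = Patient(patient_id=pid, profiles=profs)
        patient.validate()
        patients.append(patient)
    return patients


# ---------------------------------------------------------------------------
# derived classifiers


def classify_symptomatic(profile: PatientProfile) -> bool:
    """A patient is symptomatic when at least three records are flagged as
    diabetes symptoms.  The result is recorded as a derived fact."""
    count = sum(1 for r in profile.records if r.is_diabetes_symptom)
    result = count >= 3
    if result:
        profile.derived.add("symptomatic")
    return result


def classify_adult(profile: PatientProfile, threshold: int = DEFAULT_ADULT_AGE) -> bool:
    """Strictly-greater-than age threshold (default 45 years)."""
    result = profile.demographics.age > threshold
    if result:
        profile.derived.add("adult")
    return result
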