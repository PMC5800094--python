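"""Seeded synthetic patient cohorts and longitudinal follow-up trajectories.

Every pipeline stage can be exercised without clinical data: the generator
draws demographics, symptom/disease/medication prevalences, and a
two-component lab mixture (normoglycemic vs hyperglycemic), all from a single
seed.  Patient ``i`` uses the substream ``(seed, i)``, so growing a cohort
leaves earlier patients byte-identical.  The bundled single-patient case
fixture is a plain file and is independent of any seed.
"""

from __future__ import annotations

import importlib.resources
import json
import zlib
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Optional

import numpy as np

from .errors import BadCohortSpecError, NothingToFollowUpError
from .knowledge_base import KnowledgeBase, default_kb
from .plan_generator import (
    PlannerConfig,
    TreatmentPlan,
    add_months,
    follow_up,
)
from .profile_model import (
    Patient,
    PatientProfile,
    load_profile,
    write_profile,
)

DIABETES_SYMPTOMS = (
    "polyuria", "polydipsia", "polyphagia", "unexplained_weight_loss",
    "blurred_vision", "fatigue", "slow_healing_wounds",
)


@dataclass
class CohortSpec:
    n: int = 100
    seed: int = 0
    start_date: Date = Date(2017, 1, 1)
    # prevalence knobs
    symptom_probability: float = 0.25          # per diabetes symptom
    disease_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "lactic_acidosis": 0.03,
            "nonparalytic_stroke": 0.05,
            "heart_failure": 0.08,
            "renal_failure": 0.06,
            "pancreatitis": 0.02,
            "hypertension": 0.30,
            "obesity": 0.35,
            "sulfa_allergy": 0.03,
        }
    )
    medication_probabilities: dict[str, float] = field(
        default_factory=lambda: {"dofetilide": 0.03}
    )
    diabetic_fraction: float = 0.5             # hyperglycemic mixture weight
    # demographic ranges
    age_range: tuple[int, int] = (30, 80)
    height_range_cm: tuple[float, float] = (150.0, 195.0)
    weight_range_kg: tuple[float, float] = (50.0, 130.0)
    # probability that a plan of a given tier reaches target in one period
    response_model: dict[str, float] = field(
        default_factory=lambda: {
            "initial": 0.2, "mono": 0.4, "dual": 0.5,
            "triple": 0.6, "injectable": 0.7,
        }
    )

    def validate(self) -> None:
        if self.n < 0:
            raise BadCohortSpecError("n must be non-negative")
        probs = [self.symptom_probability, self.diabetic_fraction,
                 *self.disease_probabilities.values(),
                 *self.medication_probabilities.values(),
                 *self.response_model.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise BadCohortSpecError("probabilities must lie in [0, 1]")
        for lo, hi in (self.age_range, self.height_range_cm,
                       self.weight_range_kg):
            if not lo < hi:
                raise BadCohortSpecError("ranges must be non-degenerate")


def case_study_profile(kb: Optional[KnowledgeBase] = None) -> PatientProfile:
    """The bundled case patient: 50-year-old male teacher, 100 kg, 180 cm,
    light activity, low income, lactic acidosis and nonparalytic stroke on
    record, taking dofetilide.  Always identical, independent of any seed."""
    path = importlib.resources.files("diaplan") / "data" / "case_study_profile.json"
    return load_profile(json.loads(path.read_text()), kb or default_kb())


def _patient_rng(seed: int, index) -> np.random.Generator:
    if isinstance(index, str):
        index = zlib.crc32(index.encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, index])


def generate_profile(spec: CohortSpec, index: int,
                     kb: Optional[KnowledgeBase] = None) -> PatientProfile:
    """Deterministic profile for patient ``index`` under ``spec``."""
    kb = kb or default_kb()
    rng = _patient_rng(spec.seed, index)
    pid = f"syn-{index:05d}"
    age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
    sex = "male" if rng.random() < 0.5 else "female"
    height = float(np.round(rng.uniform(*spec.height_range_cm), 1))
    weight = float(np.round(rng.uniform(*spec.weight_range_kg), 1))
    social = ["poor", "intermediate", "rich"][
        int(rng.choice(3, p=[0.3, 0.5, 0.2]))
    ]
    activity = ["sedentary", "light", "moderate", "very_active",
                "extra_active"][int(rng.choice(5, p=[0.3, 0.3, 0.25, 0.1, 0.05]))]

    records = []
    for symptom in DIABETES_SYMPTOMS:
        if rng.random() < spec.symptom_probability:
            records.append({"kind": "symptom", "code": symptom})
    for disease, prob in spec.disease_probabilities.items():
        if rng.random() < prob:
            records.append({"kind": "disease", "code": disease})
    for med, prob in spec.medication_probabilities.items():
        if rng.random() < prob:
            records.append({"kind": "medication", "code": med})

    diabetic = rng.random() < spec.diabetic_fraction
    if diabetic:
        a1c = float(np.clip(rng.normal(8.4, 1.0), 6.6, 14.0))
        fpg = float(np.clip(rng.normal(170.0, 35.0), 127.0, 420.0))
    else:
        a1c = float(np.clip(rng.normal(5.3, 0.3), 4.2, 5.6))
        fpg = float(np.clip(rng.normal(90.0, 8.0), 65.0, 99.0))
    lab_date = spec.start_date - timedelta(days=5)
    document = {
        "patient_id": pid,
        "profile_id": f"{pid}-p1",
        "date": spec.start_date.isoformat(),
        "demographics": {
            "age": age, "sex": sex, "height_cm": height, "weight_kg": weight,
            "social_state": social, "activity_level": activity,
            "language": "english", "education_level": "secondary",
        },
        "labs": [
            {"test": "hba1c", "value": round(a1c, 1), "unit": "%",
             "date": lab_date.isoformat()},
            {"test": "fasting_plasma_glucose", "value": round(fpg, 0),
             "unit": "mg/dL", "date": lab_date.isoformat()},
        ],
        "records": records,
        "has_previous_treatment_plan": False,
    }
    return load_profile(document, kb)


def generate_cohort(spec: CohortSpec,
                    kb: Optional[KnowledgeBase] = None) -> list[Patient]:
    """Generate ``spec.n`` patients, each with one baseline profile.

    Deterministic for a fixed seed; every profile round-trips through
    :func:`~diaplan.profile_model.load_profile`.
    """
    spec.validate()
    kb = kb or default_kb()
    patients = []
    for i in range(spec.n):
        profile = generate_profile(spec, i, kb)
        patient = Patient(patient_id=profile.patient_id, profiles=[profile])
        patient.validate()
        patients.append(patient)
    return patients


def write_cohort(patients: list[Patient], path) -> None:
    """Write a cohort as newline-delimited JSON profile documents."""
    lines = []
    for patient in patients:
        for profile in patient.profiles:
            lines.append(json.dumps(write_profile(profile), sort_keys=True))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# longitudinal simulation


def _mutated_profile(profile: PatientProfile, new_date: Date,
                     achieved: bool, target_a1c: float,
                     kb: KnowledgeBase) -> PatientProfile:
    document = write_profile(profile)
    document["date"] = new_date.isoformat()
    document["profile_id"] = f"{profile.patient_id}-{new_date.isoformat()}"
    document["has_previous_treatment_plan"] = True
    a1c = profile.latest_lab("hba1c")
    new_a1c = (target_a1c - 0.3) if achieved else max(
        (a1c.value if a1c else 8.5), target_a1c + 1.0
    )
    document["labs"] = [
        {"test": "hba1c", "value": round(new_a1c, 1), "unit": "%",
         "date": new_date.isoformat()},
        {"test": "fasting_plasma_glucose",
         "value": 110.0 if achieved else 180.0, "unit": "mg/dL",
         "date": new_date.isoformat()},
    ]
    return load_profile(document, kb)


def simulate_followups(
    patient: Patient,
    periods: int,
    spec: CohortSpec,
    kb: Optional[KnowledgeBase] = None,
    config: Optional[PlannerConfig] = None,
) -> list[TreatmentPlan]:
    """Simulate ``periods`` three-month reviews for a patient with an
    initial plan, sampling target achievement from ``spec.response_model``.

    On a failed period the regimen is assumed to have been titrated to the
    maximum dose between visits (doses are raised before the review), so a
    persistent non-responder escalates one tier per period — the
    forced-failure trajectory walks the tier ladder to injectable therapy.
    """
    kb = kb or default_kb()
    config = config or PlannerConfig.from_kb(kb)
    if patient.active_plan is None:
        raise NothingToFollowUpError(
            f"{patient.patient_id} has no initial plan to follow"
        )
    rng = _patient_rng(spec.seed, patient.patient_id)
    trajectory = []
    for _ in range(periods):
        plan = patient.active_plan
        achieved = rng.random() < spec.response_model.get(plan.tier, 0.5)
        if not achieved:
            for prescription in plan.drug_subplan.prescriptions:
                prescription.dose = kb.drug(prescription.drug).max_dose_per_day
        review_date = add_months(plan.date, config.review_months)
        profile = _mutated_profile(
            patient.latest_profile, review_date, achieved,
            plan.target.a1c_target, kb,
        )
        patient.profiles.append(profile)
        trajectory.append(follow_up(patient, profile, kb, config))
    return trajectory
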