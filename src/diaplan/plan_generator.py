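"""Construction and temporal escalation of individualized treatment plans.

A treatment plan bundles a drug subplan (possibly empty at the initial,
lifestyle-only tier), a computed diet subplan, an exercise subplan, an
education subplan, and a target with a review date three months out.  Tiers
escalate ``initial → mono → dual → triple → injectable``; a tier is only left
upward, and only after the current regimen has failed its target at maximum
dose.  Drug choice inside a class honours contraindications (from the PCR
phase and the KB registry) and affordability (a patient with a ``poor``
social state is limited to low-cost drugs); no plan may combine two drugs of
the same class or mechanism of action.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import Optional, Sequence

from .diet_planner import DietParameters, DietSubplan, build_diet_subplan
from .errors import (
    KBConflictError,
    ManualReviewRequiredError,
    NoEligibleDrugError,
    NotIndicatedError,
    NothingToFollowUpError,
    UnresolvedCodeError,
)
from .knowledge_base import (
    Drug,
    KnowledgeBase,
    PlanTemplate,
    TIER_ORDER,
    contraindications_for,
)
from .profile_model import Patient, PatientProfile
from .rule_engine import FactBase, evaluate

_EFFICIENCY_SCORE = {"intermediate": 1, "high": 2, "highest": 3}
_RISK_SCORE = {"low": 2, "moderate": 1, "high": 0}
_WEIGHT_SCORE = {"loss": 2, "neutral": 1, "gain": 0}
_COST_SCORE = {"low": 2, "variable": 1, "high": 0}


# ---------------------------------------------------------------------------
# calendar arithmetic (whole calendar months)


def add_months(day: Date, months: int) -> Date:
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    return Date(year, month, min(day.day, calendar.monthrange(year, month)[1]))


def months_between(start: Date, end: Date) -> int:
    """Whole calendar months from start to end (floor)."""
    months = (end.year - start.year) * 12 + (end.month - start.month)
    if end.day < start.day:
        months -= 1
    return months


# ---------------------------------------------------------------------------
# plan data types


@dataclass
class Target:
    a1c_target: float
    glucose_target: float
    weight_target: float
    next_evaluation_date: Date


@dataclass
class Prescription:
    drug: str
    dose: float
    dose_unit: str
    dose_form: str
    route: str
    times_per_day: int
    duration_months: int


@dataclass
class DrugSubplan:
    prescriptions: list[Prescription] = field(default_factory=list)

    def validate(self, kb: KnowledgeBase) -> None:
        classes = [kb.drug(p.drug).drug_class for p in self.prescriptions]
        if len(set(classes)) != len(classes):
            raise KBConflictError("two prescriptions share a drug class")
        moas = [kb.mechanism_of(c) for c in classes]
        if len(set(moas)) != len(moas):
            raise KBConflictError("two prescriptions share a mechanism of action")


@dataclass
class Activity:
    type: str
    duration_min: int
    frequency_per_week: int
    intensity_pct: int
    progression: str


@dataclass
class ExerciseSubplan:
    activities: list[Activity] = field(default_factory=list)


@dataclass
class EducationSection:
    topic: str
    material_type: str
    language: str


@dataclass
class EducationSubplan:
    provider_role: str
    sections: list[EducationSection] = field(default_factory=list)


@dataclass
class TreatmentPlan:
    plan_id: str
    date: Date
    template_id: str
    tier: str
    drug_subplan: DrugSubplan
    diet_subplan: DietSubplan
    exercise_subplan: ExerciseSubplan
    education_subplan: EducationSubplan
    target: Target
    status: str = "active"  # active | target_achieved | failed
    months_elapsed: int = 0
    insulin_combination_flag: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def drug_names(self):
        return tuple(p.drug for p in self.drug_subplan.prescriptions)


@dataclass
class PlannerConfig:
    start_tier: str = "mono"  # tier for a freshly diagnosed T2DM patient
    review_months: int = 3
    a1c_target: float = 7.0
    glucose_target: float = 130.0
    weight_factor: float = 0.95
    preference_weights: dict = field(
        default_factory=lambda: {"efficiency": 1.0, "hypoglycemic_risk": 1.0,
                                 "weight_effect": 1.0, "cost": 1.0}
    )

    @classmethod
    def from_kb(cls, kb: KnowledgeBase, **overrides) -> "PlannerConfig":
        config = cls(
            review_months=int(kb.thresholds.get("review_months", 3)),
            a1c_target=float(kb.targets.get("a1c_pct", 7.0)),
            glucose_target=float(kb.targets.get("fasting_glucose_mg_dl", 130.0)),
            weight_factor=float(kb.targets.get("weight_factor", 0.95)),
            preference_weights=dict(kb.preference_weights),
        )
        for key, value in overrides.items():
            setattr(config, key, value)
        return config


# ---------------------------------------------------------------------------
# drug selection


def _is_affordable(drug: Drug, profile: PatientProfile) -> bool:
    if profile.demographics.social_state == "poor":
        return drug.cost == "low"
    return True


def select_drug_in_class(
    profile: PatientProfile, class_name: str, kb: KnowledgeBase
) -> Drug:
    """First KB-priority drug in a class with no contraindication for this
    profile and a cost the patient can bear."""
    if class_name not in kb.drug_classes:
        raise UnresolvedCodeError(f"unknown drug class {class_name!r}")
    for drug in kb.drugs_in_class(class_name):
        if contraindications_for(profile, drug.name, kb):
            continue
        if not _is_affordable(drug, profile):
            continue
        return drug
    raise NoEligibleDrugError(
        f"no eligible drug in class {class_name!r} for {profile.patient_id}"
    )


def _prescription_for(drug: Drug, review_months: int) -> Prescription:
    return Prescription(
        drug=drug.name,
        dose=float(drug.start_dose or drug.max_dose_per_day),
        dose_unit=drug.dose_unit,
        dose_form=drug.dose_form,
        route=drug.route,
        times_per_day=drug.times_per_day,
        duration_months=review_months,
    )


# ---------------------------------------------------------------------------
# subplan builders


def _build_exercise(profile: PatientProfile, kb: KnowledgeBase) -> ExerciseSubplan:
    banned: set[str] = set()
    closure: set[str] = set()
    for code in profile.diseases:
        closure.update(kb.disease_ancestors(code))
    for entry in kb.exercise.get("contraindicated", []):
        if entry["disease"] in closure:
            banned.add(entry["activity"])
    activities = [
        Activity(
            type=doc["type"],
            duration_min=int(doc["duration_min"]),
            frequency_per_week=int(doc["frequency_per_week"]),
            intensity_pct=int(doc["intensity_pct"]),
            progression=str(doc.get("progression", "")),
        )
        for doc in kb.exercise.get("default_activities", [])
        if doc["type"] not in banned
    ]
    return ExerciseSubplan(activities)


def _build_education(profile: PatientProfile, kb: KnowledgeBase) -> EducationSubplan:
    demo = profile.demographics
    basic = demo.education_level in {"none", "illiterate", "primary"}
    material = "video" if basic else "text"
    return EducationSubplan(
        provider_role=kb.education.get("provider_role", "diabetes_nurse_educator"),
        sections=[
            EducationSection(topic=t, material_type=material, language=demo.language)
            for t in kb.education.get("topics", ["diet", "physical_activity", "drugs"])
        ],
    )


def _make_target(profile: PatientProfile, plan_date: Date,
                 config: PlannerConfig) -> Target:
    return Target(
        a1c_target=config.a1c_target,
        glucose_target=config.glucose_target,
        weight_target=round(profile.demographics.weight_kg * config.weight_factor, 1),
        next_evaluation_date=add_months(plan_date, config.review_months),
    )


def _assemble(
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: PlannerConfig,
    template_id: str,
    tier: str,
    prescriptions: Sequence[Prescription],
    plan_id: str,
    insulin_flag: bool = False,
    notes: Sequence[str] = (),
) -> TreatmentPlan:
    subplan = DrugSubplan(list(prescriptions))
    subplan.validate(kb)
    plan = TreatmentPlan(
        plan_id=plan_id,
        date=profile.date,
        template_id=template_id,
        tier=tier,
        drug_subplan=subplan,
        diet_subplan=build_diet_subplan(profile, DietParameters.from_kb(kb)),
        exercise_subplan=_build_exercise(profile, kb),
        education_subplan=_build_education(profile, kb),
        target=_make_target(profile, profile.date, config),
        insulin_combination_flag=insulin_flag,
        notes=list(notes),
    )
    return plan


# ---------------------------------------------------------------------------
# new-patient planning


def _candidate_mono_classes(facts: FactBase, profile: PatientProfile,
                            kb: KnowledgeBase) -> list[str]:
    p = profile.patient_id
    suggested = {f.args[1] for f in facts.matching("suggested_class", 2)
                 if f.args[0] == p}
    ordered = [c for c in kb.class_priority if c in suggested]
    ordered += sorted(suggested - set(ordered))
    if not ordered:
        # no treatment rules fired (e.g. a pared-down rule file): fall back to
        # the KB priority list, excluding PCR-contraindicated classes
        ordered = [
            c for c in kb.class_priority
            if not facts.has("contraindicated", p, c)
        ]
    return ordered


def recommend_new_plan(
    profile: PatientProfile,
    kb: KnowledgeBase,
    facts: Optional[FactBase] = None,
    config: Optional[PlannerConfig] = None,
    plan_id: Optional[str] = None,
) -> TreatmentPlan:
    """Plan for a patient without a previous treatment plan.

    Prediabetes (or ``start_tier='initial'``) yields the lifestyle-only
    initial plan.  A T2DM diagnosis yields the monotherapy template with the
    first non-contraindicated, affordable class (biguanide first, substituting
    per the PTR suggestions otherwise).  A symptomatic severe case (glucose
    ≥ 300 mg/dL or HbA1c ≥ 10 %) flags the plan for injectable-insulin
    combination consideration.
    """
    config = config or PlannerConfig.from_kb(kb)
    if facts is None:
        facts = evaluate(profile, kb)
    p = profile.patient_id
    plan_id = plan_id or f"{p}-plan-1"
    has_t2dm = facts.has("has_diagnosis", p, "t2dm")
    has_prediabetes = facts.has("has_diagnosis", p, "prediabetes")
    if not has_t2dm and not has_prediabetes:
        raise NotIndicatedError(f"no diabetes diagnosis derived for {p}")
    insulin_flag = facts.has("consider_insulin_combination", p)

    if not has_t2dm or config.start_tier == "initial":
        return _assemble(profile, kb, config, "IP", "initial", (), plan_id,
                         insulin_flag=insulin_flag)

    for class_name in _candidate_mono_classes(facts, profile, kb):
        try:
            drug = select_drug_in_class(profile, class_name, kb)
        except NoEligibleDrugError:
            continue
        notes = []
        base = kb.template("MP").component_classes[0]
        if class_name != base:
            notes.append(f"monotherapy class substituted: {base} -> {class_name}")
        return _assemble(
            profile, kb, config, "MP", "mono",
            (_prescription_for(drug, config.review_months),),
            plan_id, insulin_flag=insulin_flag, notes=notes,
        )
    raise ManualReviewRequiredError(
        f"every candidate drug class is contraindicated for {p}"
    )


# ---------------------------------------------------------------------------
# follow-up and escalation


def _target_achieved(profile: PatientProfile, target: Target) -> bool:
    a1c = profile.latest_lab("hba1c")
    if a1c is not None:
        return a1c.value <= target.a1c_target
    glucose = profile.latest_lab("fasting_plasma_glucose")
    if glucose is not None:
        return glucose.value <= target.glucose_target
    return False


def _dual_preference(template: PlanTemplate, weights: dict) -> float:
    ch = template.characteristics
    if ch is None:
        return 0.0
    return (
        weights.get("efficiency", 1.0) * _EFFICIENCY_SCORE[ch.efficiency]
        + weights.get("hypoglycemic_risk", 1.0) * _RISK_SCORE[ch.hypoglycemic_risk]
        + weights.get("weight_effect", 1.0) * _WEIGHT_SCORE[ch.weight_effect]
        + weights.get("cost", 1.0) * _COST_SCORE[ch.cost]
    )


def _escalate(
    plan: TreatmentPlan,
    profile: PatientProfile,
    kb: KnowledgeBase,
    facts: FactBase,
    config: PlannerConfig,
    plan_id: str,
) -> TreatmentPlan:
    tier_index = TIER_ORDER.index(plan.tier)
    if plan.tier == "injectable":
        renewed = _renew(plan, profile, kb, config, plan_id)
        renewed.notes.append("already at the highest tier; plan renewed for review")
        return renewed
    next_tier = TIER_ORDER[tier_index + 1]
    insulin_flag = facts.has("consider_insulin_combination", profile.patient_id)

    if next_tier == "mono":
        mono_config = replace(config, start_tier="mono")
        fresh = recommend_new_plan(profile, kb, facts=facts, config=mono_config,
                                   plan_id=plan_id)
        fresh.notes.append("escalated from lifestyle-only initial plan")
        return fresh

    current = {p.drug: kb.drug(p.drug).drug_class
               for p in plan.drug_subplan.prescriptions}
    current_classes = set(current.values())
    current_moas = {kb.mechanism_of(c) for c in current_classes}

    if next_tier == "injectable":
        # injectable regimens replace the oral stack (lifestyle + insulin-based)
        for template in kb.templates:
            if template.tier != "injectable":
                continue
            try:
                drugs = [select_drug_in_class(profile, c, kb)
                         for c in template.component_classes]
            except NoEligibleDrugError:
                continue
            return _assemble(
                profile, kb, config, template.template_id, "injectable",
                [_prescription_for(d, config.review_months) for d in drugs],
                plan_id, insulin_flag=insulin_flag,
                notes=["oral regimen replaced by injectable therapy"],
            )
        raise ManualReviewRequiredError("no eligible injectable combination")

    candidates: list[tuple[tuple, PlanTemplate, Drug]] = []
    for order, template in enumerate(kb.templates):
        if template.tier != next_tier:
            continue
        added = template.component_classes[-1]
        if added in current_classes:
            continue
        if kb.mechanism_of(added) in current_moas:
            continue
        if contraindications_for(profile, added, kb):
            continue
        try:
            drug = select_drug_in_class(profile, added, kb)
        except NoEligibleDrugError:
            continue
        prefix_matches = set(template.component_classes[:-1]) == current_classes
        if next_tier == "dual":
            rank = (-_dual_preference(template, config.preference_weights),
                    template.template_id)
        else:
            # prefer templates built on the patient's actual current combo
            rank = (0 if prefix_matches else 1, order, template.template_id)
        candidates.append((rank, template, drug))
    if not candidates:
        raise ManualReviewRequiredError(
            f"no eligible {next_tier}-tier combination for {profile.patient_id}"
        )
    candidates.sort(key=lambda item: item[0])
    _, template, drug = candidates[0]

    kept = [replace(p, duration_months=config.review_months)
            for p in plan.drug_subplan.prescriptions]
    prescriptions = kept + [_prescription_for(drug, config.review_months)]
    exact = set(template.component_classes) == current_classes | {
        template.component_classes[-1]
    }
    template_id = template.template_id if exact else template.template_id + "*"
    notes = [] if exact else [
        "template adapted to the substituted current regimen"
    ]
    return _assemble(profile, kb, config, template_id, next_tier,
                     prescriptions, plan_id, insulin_flag=insulin_flag,
                     notes=notes)


def _renew(plan: TreatmentPlan, profile: PatientProfile, kb: KnowledgeBase,
           config: PlannerConfig, plan_id: str) -> TreatmentPlan:
    prescriptions = [replace(p, duration_months=config.review_months)
                     for p in plan.drug_subplan.prescriptions]
    return _assemble(profile, kb, config, plan.template_id, plan.tier,
                     prescriptions, plan_id,
                     insulin_flag=plan.insulin_combination_flag)


def follow_up(
    patient: Patient,
    current_profile: PatientProfile,
    kb: KnowledgeBase,
    config: Optional[PlannerConfig] = None,
) -> TreatmentPlan:
    """Three-month review of the active plan.

    Target achieved → the plan is renewed unchanged for another review
    period.  Target missed with any dose below its maximum → same regimen
    with doses stepped toward the maximum.  Target missed at maximum dose →
    escalate one tier.  The new plan is appended to the patient's history.
    """
    config = config or PlannerConfig.from_kb(kb)
    plan = patient.active_plan
    if plan is None:
        raise NothingToFollowUpError(f"{patient.patient_id} has no active plan")
    elapsed = months_between(plan.date, current_profile.date)
    if elapsed < config.review_months:
        raise NothingToFollowUpError(
            f"review window not reached ({elapsed} < {config.review_months} months)"
        )
    plan.months_elapsed = elapsed
    plan_id = f"{patient.patient_id}-plan-{len(patient.plans) + 1}"
    facts = evaluate(current_profile, kb)

    if _target_achieved(current_profile, plan.target):
        plan.status = "target_achieved"
        new_plan = _renew(plan, current_profile, kb, config, plan_id)
        new_plan.notes.append("target achieved; plan renewed")
    else:
        plan.status = "failed"
        titratable = [
            p for p in plan.drug_subplan.prescriptions
            if p.dose < kb.drug(p.drug).max_dose_per_day
        ]
        if titratable:
            prescriptions = []
            for p in plan.drug_subplan.prescriptions:
                drug = kb.drug(p.drug)
                step = drug.dose_step or drug.max_dose_per_day
                dose = min(p.dose + step, drug.max_dose_per_day)
                prescriptions.append(
                    replace(p, dose=dose, duration_months=config.review_months)
                )
            new_plan = _assemble(
                current_profile, kb, config, plan.template_id, plan.tier,
                prescriptions, plan_id,
                insulin_flag=plan.insulin_combination_flag,
                notes=["dose titrated toward maximum"],
            )
        else:
            new_plan = _escalate(plan, current_profile, kb, facts, config,
                                 plan_id)
    patient.plans.append(new_plan)
    return new_plan
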