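"""Plan report writers: machine-readable JSON and a human-readable text view."""

from __future__ import annotations

import json
from typing import Optional

from .diet_planner import NUTRIENT_ORDER
from .knowledge_base import KnowledgeBase, contraindications_for
from .plan_generator import TreatmentPlan
from .profile_model import PatientProfile
from .rule_engine import FactBase


def plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "plan_id": plan.plan_id,
        "date": plan.date.isoformat(),
        "template_id": plan.template_id,
        "tier": plan.tier,
        "status": plan.status,
        "months_elapsed": plan.months_elapsed,
        "insulin_combination_flag": plan.insulin_combination_flag,
        "notes": plan.notes,
        "drug_subplan": [
            {
                "drug": p.drug,
                "dose": p.dose,
                "dose_unit": p.dose_unit,
                "dose_form": p.dose_form,
                "route": p.route,
                "times_per_day": p.times_per_day,
                "duration_months": p.duration_months,
            }
            for p in plan.drug_subplan.prescriptions
        ],
        "diet_subplan": {
            "bmr_kcal": plan.diet_subplan.bmr,
            "total_calories_kcal": plan.diet_subplan.total_calories,
            "meals": [
                {
                    "name": meal.name,
                    "kcal": meal.kcal,
                    "nutrient_kcal": meal.nutrient_kcal,
                    "nutrient_grams": meal.nutrient_grams,
                }
                for meal in plan.diet_subplan.meals
            ],
        },
        "exercise_subplan": [
            {
                "type": a.type,
                "duration_min": a.duration_min,
                "frequency_per_week": a.frequency_per_week,
                "intensity_pct": a.intensity_pct,
                "progression": a.progression,
            }
            for a in plan.exercise_subplan.activities
        ],
        "education_subplan": {
            "provider_role": plan.education_subplan.provider_role,
            "sections": [
                {"topic": s.topic, "material_type": s.material_type,
                 "language": s.language}
                for s in plan.education_subplan.sections
            ],
        },
        "target": {
            "a1c_pct": plan.target.a1c_target,
            "fasting_glucose_mg_dl": plan.target.glucose_target,
            "weight_kg": plan.target.weight_target,
            "next_evaluation_date": plan.target.next_evaluation_date.isoformat(),
        },
    }


def report_document(
    plan: TreatmentPlan,
    profile: PatientProfile,
    kb: KnowledgeBase,
    facts: Optional[FactBase] = None,
    explain: bool = False,
) -> dict:
    """Full machine report: diagnosis summary, contraindication audit, the
    plan itself, and (optionally) per-conclusion derivation chains."""
    doc = {
        "patient_id": profile.patient_id,
        "profile_id": profile.profile_id,
        "diagnosis": sorted(
            tag.split(":", 1)[1]
            for tag in profile.derived
            if tag.startswith("diagnosis:")
        ),
        "derived": sorted(profile.derived),
        "contraindication_audit": [
            {
                "prescribed_drug": p.drug,
                "matches": [
                    {"subject": ci.subject, "kind": ci.kind,
                     "object": ci.object, "note": ci.note}
                    for ci in contraindications_for(profile, p.drug, kb)
                ],
            }
            for p in plan.drug_subplan.prescriptions
        ],
        "plan": plan_to_dict(plan),
    }
    if explain and facts is not None:
        chains = []
        for predicate in ("symptomatic", "adult", "severe_case"):
            for fact in facts.matching(predicate, 1):
                chains.append(facts.explanation_dict(fact))
        for predicate in ("has_diagnosis", "contraindicated", "suggested_class"):
            for fact in facts.matching(predicate, 2):
                if fact.args[0] == profile.patient_id:
                    chains.append(facts.explanation_dict(fact))
        doc["explanations"] = chains
    return doc


def render_text(doc: dict) -> str:
    """Formatted human-readable report for one plan document."""
    plan = doc["plan"]
    lines = []
    lines.append(f"Treatment plan {plan['plan_id']} ({plan['date']})")
    lines.append(f"  template {plan['template_id']}  tier {plan['tier']}"
                 f"  status {plan['status']}")
    if plan["insulin_combination_flag"]:
        lines.append("  ** severe case: consider injectable insulin combination **")
    lines.append("")
    lines.append(f"Diagnosis: {', '.join(doc['diagnosis']) or 'none derived'}")
    flagged = [a for a in doc["contraindication_audit"] if a["matches"]]
    lines.append(f"Contraindication audit: "
                 f"{'CLEAN' if not flagged else 'VIOLATIONS PRESENT'}")
    lines.append("")
    lines.append("Prescriptions:")
    if not plan["drug_subplan"]:
        lines.append("  (lifestyle and education only)")
    for p in plan["drug_subplan"]:
        lines.append(
            f"  {p['drug']:<18} {p['dose']:g} {p['dose_unit']} "
            f"{p['dose_form']}, {p['route']}, {p['times_per_day']}x/day, "
            f"{p['duration_months']} months"
        )
    diet = plan["diet_subplan"]
    lines.append("")
    lines.append(
        f"Diet: BMR {diet['bmr_kcal']:.2f} kcal/24h, "
        f"total {diet['total_calories_kcal']:.2f} kcal/24h"
    )
    header = f"  {'meal':<10}{'kcal':>10}" + "".join(
        f"{nut + ' g':>16}" for nut in NUTRIENT_ORDER
    )
    lines.append(header)
    for meal in diet["meals"]:
        row = f"  {meal['name']:<10}{meal['kcal']:>10.3f}" + "".join(
            f"{meal['nutrient_grams'][nut]:>16d}" for nut in NUTRIENT_ORDER
        )
        lines.append(row)
    lines.append("")
    lines.append("Exercise:")
    for a in plan["exercise_subplan"]:
        lines.append(
            f"  {a['type']:<12} {a['duration_min']} min x "
            f"{a['frequency_per_week']}/week @ {a['intensity_pct']}%"
        )
    edu = plan["education_subplan"]
    lines.append(
        f"Education ({edu['provider_role']}): "
        + ", ".join(f"{s['topic']} [{s['material_type']}, {s['language']}]"
                    for s in edu["sections"])
    )
    target = plan["target"]
    lines.append(
        f"Target: HbA1c <= {target['a1c_pct']}%, "
        f"FPG <= {target['fasting_glucose_mg_dl']} mg/dL, "
        f"weight {target['weight_kg']} kg; "
        f"review {target['next_evaluation_date']}"
    )
    return "\n".join(lines) + "\n"


def dump_json(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True)
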