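"""Plan construction, drug selection under contraindications and cost,
follow-up titration, and tier escalation."""

from datetime import date as Date

import pytest

from diaplan import (
    Patient,
    PlannerConfig,
    follow_up,
    load_profile,
    recommend_new_plan,
    select_drug_in_class,
)
from diaplan.errors import (
    KBConflictError,
    ManualReviewRequiredError,
    NoEligibleDrugError,
    NotIndicatedError,
    NothingToFollowUpError,
)
from diaplan.plan_generator import DrugSubplan, Prescription, add_months, months_between

from conftest import make_profile_doc


def diabetic_doc(**overrides):
    overrides.setdefault("labs", [
        {"test": "hba1c", "value": 8.5, "unit": "%", "date": "2017-05-25"}
    ])
    return make_profile_doc(**overrides)


class TestCalendarArithmetic:
    @pytest.mark.parametrize("start,months,expected", [
        (Date(2017, 1, 15), 3, Date(2017, 4, 15)),
        (Date(2017, 1, 31), 1, Date(2017, 2, 28)),
        (Date(2016, 11, 30), 3, Date(2017, 2, 28)),
        (Date(2017, 10, 1), 6, Date(2018, 4, 1)),
    ])
    def test_add_months(self, start, months, expected):
        assert add_months(start, months) == expected

    @pytest.mark.parametrize("a,b,expected", [
        (Date(2017, 1, 15), Date(2017, 4, 15), 3),
        (Date(2017, 1, 15), Date(2017, 4, 14), 2),
        (Date(2017, 1, 15), Date(2018, 1, 15), 12),
    ])
    def test_months_between(self, a, b, expected):
        assert months_between(a, b) == expected


class TestSelectDrugInClass:
    def test_case_sulfonylurea_yields_glimepiride(self, kb, case_profile):
        assert select_drug_in_class(case_profile, "sulfonylurea",
                                    kb).name == "glimepiride"

    def test_case_biguanide_has_no_eligible_drug(self, kb, case_profile):
        with pytest.raises(NoEligibleDrugError):
            select_drug_in_class(case_profile, "biguanide", kb)

    def test_poor_patient_cannot_buy_expensive_class(self, kb):
        poor = load_profile(make_profile_doc(social_state="poor"), kb)
        with pytest.raises(NoEligibleDrugError):
            select_drug_in_class(poor, "dpp4_inhibitor", kb)

    def test_rich_patient_gets_expensive_drug(self, kb):
        rich = load_profile(make_profile_doc(social_state="rich"), kb)
        assert select_drug_in_class(rich, "dpp4_inhibitor",
                                    kb).name == "sitagliptin"


class TestRecommendNewPlan:
    def test_case_study_monotherapy(self, kb, case_profile):
        plan = recommend_new_plan(case_profile, kb)
        assert plan.template_id == "MP"
        assert plan.tier == "mono"
        assert [p.drug for p in plan.drug_subplan.prescriptions] == [
            "glimepiride"
        ]
        assert plan.diet_subplan.total_calories == pytest.approx(2755.46)
        assert plan.target.next_evaluation_date == add_months(plan.date, 3)

    def test_prescription_carries_dose_form_route_times(self, kb, case_profile):
        [p] = recommend_new_plan(case_profile, kb).drug_subplan.prescriptions
        assert (p.dose_form, p.route, p.times_per_day) == ("tablet", "oral", 1)
        assert p.dose > 0 and p.duration_months == 3

    def test_severe_case_flags_insulin_combination(self, kb):
        doc = diabetic_doc(
            labs=[
                {"test": "hba1c", "value": 11.0, "unit": "%",
                 "date": "2017-05-25"},
                {"test": "random_plasma_glucose", "value": 320,
                 "unit": "mg/dL", "date": "2017-05-25"},
            ],
            records=[{"kind": "symptom", "code": c}
                     for c in ("polyuria", "polydipsia", "polyphagia")],
        )
        plan = recommend_new_plan(load_profile(doc, kb), kb)
        assert plan.insulin_combination_flag is True

    def test_prediabetic_gets_lifestyle_only_initial_plan(self, kb):
        doc = make_profile_doc(labs=[
            {"test": "hba1c", "value": 6.0, "unit": "%", "date": "2017-05-25"}
        ])
        plan = recommend_new_plan(load_profile(doc, kb), kb)
        assert plan.template_id == "IP"
        assert plan.tier == "initial"
        assert plan.drug_subplan.prescriptions == []
        assert plan.diet_subplan.meals  # lifestyle subplan still present

    def test_healthy_profile_not_indicated(self, kb):
        profile = load_profile(make_profile_doc(labs=[
            {"test": "hba1c", "value": 5.2, "unit": "%", "date": "2017-05-25"}
        ]), kb)
        with pytest.raises(NotIndicatedError):
            recommend_new_plan(profile, kb)

    def test_all_classes_blocked_requires_manual_review(self, kb):
        # poor patient (low-cost classes only) with diseases/drugs blocking
        # biguanide, sulfonylurea, thiazolidinedione; remaining low-cost
        # classes are not PTR-suggested and the expensive ones unaffordable
        doc = diabetic_doc(
            social_state="poor",
            records=[
                {"kind": "disease", "code": "lactic_acidosis"},
                {"kind": "disease", "code": "heart_failure"},
                {"kind": "disease", "code": "sulfa_allergy"},
            ],
        )
        with pytest.raises(ManualReviewRequiredError):
            recommend_new_plan(load_profile(doc, kb), kb)

    def test_subplan_rejects_shared_mechanism(self, kb):
        subplan = DrugSubplan([
            Prescription("glimepiride", 1, "mg", "tablet", "oral", 1, 3),
            Prescription("glipizide", 5, "mg", "tablet", "oral", 2, 3),
        ])
        with pytest.raises(KBConflictError):
            subplan.validate(kb)

    def test_exercise_contraindication_filters_aerobics(self, kb):
        doc = diabetic_doc(
            records=[{"kind": "disease", "code": "chronic_bronchitis"}]
        )
        plan = recommend_new_plan(load_profile(doc, kb), kb)
        types = {a.type for a in plan.exercise_subplan.activities}
        assert "aerobics" not in types and "resistance" in types

    def test_education_language_follows_profile(self, kb):
        doc = diabetic_doc(language="arabic")
        plan = recommend_new_plan(load_profile(doc, kb), kb)
        assert all(s.language == "arabic"
                   for s in plan.education_subplan.sections)


def patient_with_plan(kb, **overrides):
    profile = load_profile(diabetic_doc(**overrides), kb)
    patient = Patient(patient_id=profile.patient_id, profiles=[profile])
    patient.plans.append(recommend_new_plan(profile, kb))
    return patient


def later_profile(kb, patient, a1c, months=3, **overrides):
    base = make_profile_doc(
        patient_id=patient.patient_id,
        date=add_months(patient.profiles[-1].date, months).isoformat(),
        has_previous_treatment_plan=True,
        labs=[{"test": "hba1c", "value": a1c, "unit": "%",
               "date": add_months(patient.profiles[-1].date,
                                  months).isoformat()}],
        **overrides,
    )
    profile = load_profile(base, kb)
    patient.profiles.append(profile)
    return profile


class TestFollowUp:
    def test_achieved_target_renews_same_prescriptions(self, kb):
        patient = patient_with_plan(kb)
        old = patient.active_plan
        profile = later_profile(kb, patient, a1c=6.5)
        new = follow_up(patient, profile, kb)
        assert old.status == "target_achieved"
        assert new.template_id == old.template_id
        assert [(p.drug, p.dose) for p in new.drug_subplan.prescriptions] == [
            (p.drug, p.dose) for p in old.drug_subplan.prescriptions
        ]
        assert new.target.next_evaluation_date == add_months(profile.date, 3)

    def test_failure_below_max_titrates_dose(self, kb):
        patient = patient_with_plan(kb)
        old_dose = patient.active_plan.drug_subplan.prescriptions[0].dose
        profile = later_profile(kb, patient, a1c=8.4)
        new = follow_up(patient, profile, kb)
        assert old_dose < new.drug_subplan.prescriptions[0].dose
        assert new.tier == "mono"
        assert patient.plans[0].status == "failed"

    def test_failure_at_max_dose_escalates_to_dual(self, kb):
        patient = patient_with_plan(kb)
        drug = patient.active_plan.drug_subplan.prescriptions[0]
        drug.dose = kb.drug(drug.drug).max_dose_per_day
        profile = later_profile(kb, patient, a1c=8.4)
        new = follow_up(patient, profile, kb)
        assert new.tier == "dual"
        # table-driven preference picks the low-risk, low-cost combination
        assert new.template_id == "DTP-2"
        assert len(new.drug_subplan.prescriptions) == 2
        new.drug_subplan.validate(kb)

    def test_escalation_skips_contraindicated_added_class(self, kb):
        patient = patient_with_plan(
            kb, records=[{"kind": "disease", "code": "heart_failure"}]
        )
        drug = patient.active_plan.drug_subplan.prescriptions[0]
        drug.dose = kb.drug(drug.drug).max_dose_per_day
        profile = later_profile(
            kb, patient, a1c=8.4,
            records=[{"kind": "disease", "code": "heart_failure"}],
        )
        new = follow_up(patient, profile, kb)
        assert new.tier == "dual"
        added = {kb.drug(p.drug).drug_class
                 for p in new.drug_subplan.prescriptions}
        assert "thiazolidinedione" not in added

    def test_dual_failure_adds_mechanism_distinct_third_class(self, kb):
        patient = patient_with_plan(kb, social_state="rich")
        for _ in range(2):  # walk to a dual plan at maximum dose
            for p in patient.active_plan.drug_subplan.prescriptions:
                p.dose = kb.drug(p.drug).max_dose_per_day
            profile = later_profile(kb, patient, a1c=8.4)
            follow_up(patient, profile, kb)
        plan = patient.active_plan
        assert plan.tier == "triple"
        classes = [kb.drug(p.drug).drug_class
                   for p in plan.drug_subplan.prescriptions]
        moas = [kb.mechanism_of(c) for c in classes]
        assert len(set(moas)) == 3

    def test_no_active_plan_raises(self, kb):
        profile = load_profile(diabetic_doc(), kb)
        patient = Patient(patient_id=profile.patient_id, profiles=[profile])
        with pytest.raises(NothingToFollowUpError):
            follow_up(patient, profile, kb)

    def test_review_window_not_reached_raises(self, kb):
        patient = patient_with_plan(kb)
        early = later_profile(kb, patient, a1c=8.4, months=1)
        with pytest.raises(NothingToFollowUpError):
            follow_up(patient, early, kb)

    def test_tier_never_descends_without_achievement(self, kb):
        patient = patient_with_plan(kb, social_state="rich")
        from diaplan.knowledge_base import TIER_ORDER

        for _ in range(5):
            for p in patient.active_plan.drug_subplan.prescriptions:
                p.dose = kb.drug(p.drug).max_dose_per_day
            profile = later_profile(kb, patient, a1c=8.4)
            follow_up(patient, profile, kb)
        tiers = [TIER_ORDER.index(plan.tier) for plan in patient.plans]
        assert tiers == sorted(tiers)
        assert patient.plans[-1].tier == "injectable"
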