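"""Knowledge-base loading, template expansion, contraindication matching,
and cohort competency queries."""

import copy

import pytest

from diaplan import (
    contraindications_for,
    enumerate_medication_plans,
    load_kb,
    load_profile,
    query_cohort,
    write_kb,
)
from diaplan.errors import (
    KBConflictError,
    UnresolvedCodeError,
    UnsupportedQueryError,
)
from diaplan.profile_model import Patient

from conftest import make_profile_doc


def raw_kb_copy(kb):
    return copy.deepcopy(kb.raw)


class TestLoadKB:
    def test_bundled_kb_has_nine_diabetes_classes(self, kb):
        assert len(kb.diabetes_classes()) == 9

    def test_tier_counts(self, kb):
        counts = {tier: len(enumerate_medication_plans(kb, tier))
                  for tier in ("mono", "dual", "triple", "injectable")}
        assert counts == {"mono": 1, "dual": 6, "triple": 25, "injectable": 2}
        assert len(enumerate_medication_plans(kb)) == 34

    def test_no_template_shares_class_or_mechanism(self, kb):
        for template in kb.templates:
            classes = template.component_classes
            assert len(set(classes)) == len(classes), template.template_id
            moas = [kb.mechanism_of(c) for c in classes]
            assert len(set(moas)) == len(moas), template.template_id

    def test_duplicate_class_in_template_is_conflict(self, kb):
        raw = raw_kb_copy(kb)
        raw["plan_templates"]["injectable"].append(
            {"id": "ITP-X", "components": ["sulfonylurea", "sulfonylurea"]}
        )
        with pytest.raises(KBConflictError):
            load_kb(raw)

    def test_shared_mechanism_in_template_is_conflict(self, kb):
        raw = raw_kb_copy(kb)
        raw["plan_templates"]["injectable"].append(
            {"id": "ITP-X",
             "components": ["dpp4_inhibitor", "glp1_receptor_agonist"]}
        )
        with pytest.raises(KBConflictError):
            load_kb(raw)

    def test_duplicate_template_id_is_conflict(self, kb):
        raw = raw_kb_copy(kb)
        raw["plan_templates"]["injectable"].append(
            {"id": "ITP-1", "components": ["sulfonylurea"]}
        )
        with pytest.raises(KBConflictError):
            load_kb(raw)

    def test_unknown_disease_reference_unresolved(self, kb):
        raw = raw_kb_copy(kb)
        raw["contraindications"].append(
            {"subject": "biguanide", "kind": "drug_disease",
             "object": "imaginary_disease"}
        )
        with pytest.raises(UnresolvedCodeError):
            load_kb(raw)

    def test_load_write_load_idempotent(self, kb, tmp_path):
        path = tmp_path / "kb.yaml"
        write_kb(kb, path)
        again = load_kb(path)
        assert again.diabetes_classes() == kb.diabetes_classes()
        assert [t.template_id for t in again.templates] == [
            t.template_id for t in kb.templates
        ]
        assert again.contraindications == kb.contraindications
        assert sorted(again.drugs) == sorted(kb.drugs)

    def test_disease_subsumption_closure(self, kb):
        assert "cerebrovascular_disease" in kb.disease_ancestors(
            "nonparalytic_stroke"
        )
        assert "nonparalytic_stroke" in kb.disease_ancestors(
            "nonparalytic_stroke"
        )


class TestContraindicationsFor:
    def test_case_biguanide_two_records(self, kb, case_profile):
        hits = contraindications_for(case_profile, "biguanide", kb)
        assert {(h.kind, h.object) for h in hits} == {
            ("drug_disease", "lactic_acidosis"),
            ("drug_drug", "dofetilide"),
        }

    def test_case_metformin_inherits_class_contraindications(
        self, kb, case_profile
    ):
        hits = contraindications_for(case_profile, "metformin", kb)
        assert len(hits) == 2

    def test_case_sulfonylurea_clear(self, kb, case_profile):
        assert contraindications_for(case_profile, "sulfonylurea", kb) == []

    def test_clean_profile_matches_nothing(self, kb):
        profile = load_profile(make_profile_doc(), kb)
        assert contraindications_for(profile, "biguanide", kb) == []

    def test_unknown_target_unresolved(self, kb, case_profile):
        with pytest.raises(UnresolvedCodeError):
            contraindications_for(case_profile, "unobtainium", kb)

    def test_subsumption_reaches_super_disease_rule(self, kb):
        """A contraindication stated against a parent disease matches a
        patient recorded with the child disease."""
        raw = raw_kb_copy(kb)
        raw["contraindications"].append(
            {"subject": "sulfonylurea", "kind": "drug_disease",
             "object": "cerebrovascular_disease"}
        )
        kb2 = load_kb(raw)
        profile = load_profile(
            make_profile_doc(
                records=[{"kind": "disease", "code": "nonparalytic_stroke"}]
            ),
            kb2,
        )
        hits = contraindications_for(profile, "sulfonylurea", kb2)
        assert [h.object for h in hits] == ["cerebrovascular_disease"]

    def test_agrees_with_brute_force_scan(self, kb):
        """Oracle: exhaustive cross product of profile records x the KB
        contraindication table, with an independent ancestor walk."""
        from diaplan.synthetic_cohort import CohortSpec, generate_cohort

        def oracle(profile, target):
            if target in kb.drugs:
                subjects = {target}
                cls = kb.drugs[target].drug_class
                while cls is not None:
                    subjects.add(cls)
                    cls = kb.drug_classes[cls].parent
            else:
                subjects = {target}
                for other in kb.drug_classes:
                    chain = [other]
                    while kb.drug_classes[chain[-1]].parent:
                        chain.append(kb.drug_classes[chain[-1]].parent)
                    if target in chain:
                        subjects.update(chain)
                subjects.update(
                    d.name for d in kb.drugs.values()
                    if d.drug_class in subjects
                )
            hits = set()
            for ci in kb.contraindications:
                if ci.subject not in subjects:
                    continue
                for record in profile.records:
                    if record.kind == "disease" and ci.kind == "drug_disease":
                        ancestors = {record.code}
                        frontier = [record.code]
                        while frontier:
                            for parent in kb.disease_parents.get(
                                frontier.pop(), ()
                            ):
                                if parent not in ancestors:
                                    ancestors.add(parent)
                                    frontier.append(parent)
                        if ci.object in ancestors:
                            hits.add(ci)
                    elif (record.kind == "medication"
                          and ci.kind == "drug_drug"
                          and ci.object == record.code):
                        hits.add(ci)
            return hits

        cohort = generate_cohort(CohortSpec(n=40, seed=11), kb)
        targets = kb.diabetes_classes() + ["metformin", "glimepiride"]
        for patient in cohort:
            profile = patient.latest_profile
            for target in targets:
                assert set(contraindications_for(profile, target, kb)) == \
                    oracle(profile, target), (patient.patient_id, target)


class TestQueryCohort:
    def _patient(self, kb, pid, **overrides):
        profile = load_profile(
            make_profile_doc(patient_id=pid, **overrides), kb
        )
        return Patient(patient_id=pid, profiles=[profile])

    def test_achieved_goals_selects_only_matured_success(self, kb, case_profile):
        from diaplan import recommend_new_plan

        winner = self._patient(kb, "w",
                               labs=[{"test": "hba1c", "value": 8.0,
                                      "unit": "%", "date": "2017-05-01"}])
        plan = recommend_new_plan(winner.latest_profile, kb)
        plan.status = "target_achieved"
        plan.months_elapsed = 3
        winner.plans.append(plan)

        fresh = self._patient(kb, "f",
                              labs=[{"test": "hba1c", "value": 8.0,
                                     "unit": "%", "date": "2017-05-01"}])
        young_plan = recommend_new_plan(fresh.latest_profile, kb)
        young_plan.status = "target_achieved"
        young_plan.months_elapsed = 1  # too early to count
        fresh.plans.append(young_plan)

        assert query_cohort([winner, fresh], "achieved_goals", kb=kb) == ["w"]

    def test_taking_drug_matches_active_prescription(self, kb, case_profile):
        from diaplan import Patient, recommend_new_plan

        patient = Patient(patient_id=case_profile.patient_id,
                          profiles=[case_profile])
        patient.plans.append(recommend_new_plan(case_profile, kb))
        assert query_cohort([patient], "taking_drug", "glimepiride",
                            kb=kb) == ["patient_1"]
        assert query_cohort([patient], "taking_drug", "metformin", kb=kb) == []

    def test_diagnosed_untreated(self, kb):
        diagnosed = self._patient(kb, "d",
                                  labs=[{"test": "hba1c", "value": 9.0,
                                         "unit": "%", "date": "2017-05-01"}])
        healthy = self._patient(kb, "h",
                                labs=[{"test": "hba1c", "value": 5.0,
                                       "unit": "%", "date": "2017-05-01"}])
        assert query_cohort([diagnosed, healthy], "diagnosed_untreated",
                            kb=kb) == ["d"]

    def test_has_disease_honours_subsumption(self, kb):
        stroke = self._patient(
            kb, "s",
            records=[{"kind": "disease", "code": "nonparalytic_stroke"}],
        )
        assert query_cohort([stroke], "has_disease",
                            "cerebrovascular_disease", kb=kb) == ["s"]

    def test_empty_cohort(self, kb):
        assert query_cohort([], "achieved_goals", kb=kb) == []

    def test_unknown_selector(self, kb):
        with pytest.raises(UnsupportedQueryError):
            query_cohort([], "who_is_tallest", kb=kb)
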