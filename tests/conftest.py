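import pytest

from diaplan import default_kb, evaluate
from diaplan.synthetic_cohort import case_study_profile


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture
def case_profile(kb):
    # fresh instance per test: derived facts are mutated by the rule engine
    return case_study_profile(kb)


@pytest.fixture
def case_facts(kb, case_profile):
    return evaluate(case_profile, kb)


def make_profile_doc(**overrides):
    """A clean, valid baseline profile document for tests to perturb."""
    doc = {
        "patient_id": "t-001",
        "date": "2017-06-01",
        "demographics": {
            "age": 55,
            "sex": "female",
            "height_cm": 165.0,
            "weight_kg": 80.0,
            "social_state": "intermediate",
            "activity_level": "moderate",
            "language": "english",
            "education_level": "secondary",
        },
        "labs": [],
        "records": [],
        "has_previous_treatment_plan": False,
    }
    for key, value in overrides.items():
        if key in doc["demographics"]:
            doc["demographics"][key] = value
        else:
            doc[key] = value
    return doc
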