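"""File-backed treatment knowledge: drug taxonomy, contraindications, templates.

The knowledge base is a single YAML document (see ``data/default_kb.yaml``)
holding the controlled vocabulary, the nine top-level diabetes drug classes and
their exemplar drugs, the contraindication registry, the plan-template blocks
(monotherapy, six dual-therapy combinations, the triple-therapy option lists,
two injectable combinations), diet parameters, escalation thresholds, and the
rule set consumed by :mod:`diaplan.rule_engine`.

Plan templates are stored generatively (a dual block per added class, a triple
block per option list) and expanded at load into one
:class:`PlanTemplate` per concrete drug-class combination — 34 medication
plans with the bundled knowledge.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .errors import (
    KBConflictError,
    UnknownCodeError,
    UnresolvedCodeError,
    UnsupportedQueryError,
)
from .profile_model import ClinicalRecord, Patient, PatientProfile

TIER_ORDER = ("initial", "mono", "dual", "triple", "injectable")

EFFICIENCY_LEVELS = frozenset({"intermediate", "high", "highest"})
RISK_LEVELS = frozenset({"low", "moderate", "high"})
WEIGHT_EFFECTS = frozenset({"gain", "neutral", "loss"})
COST_LEVELS = frozenset({"low", "high", "variable"})


@dataclass(frozen=True)
class ClassCharacteristics:
    efficiency: str
    hypoglycemic_risk: str
    weight_effect: str
    side_effects: tuple[str, ...]
    cost: str

    def validate(self, where: str) -> None:
        if self.efficiency not in EFFICIENCY_LEVELS:
            raise KBConflictError(f"{where}: bad efficiency {self.efficiency!r}")
        if self.hypoglycemic_risk not in RISK_LEVELS:
            raise KBConflictError(f"{where}: bad risk {self.hypoglycemic_risk!r}")
        if self.weight_effect not in WEIGHT_EFFECTS:
            raise KBConflictError(f"{where}: bad weight effect {self.weight_effect!r}")
        if self.cost not in COST_LEVELS:
            raise KBConflictError(f"{where}: bad cost {self.cost!r}")


@dataclass
class DrugClass:
    name: str
    mechanism_of_action: str
    diabetes: bool = False
    parent: Optional[str] = None
    characteristics: Optional[ClassCharacteristics] = None


@dataclass
class Drug:
    name: str
    drug_class: str
    max_dose_per_day: float
    dose_unit: str = "mg"
    start_dose: Optional[float] = None
    dose_step: Optional[float] = None
    dose_form: str = "tablet"
    route: str = "oral"
    times_per_day: int = 1
    cost: str = "low"
    a1c_lowering: Optional[float] = None
    is_diabetes_drug: bool = True


@dataclass(frozen=True)
class Contraindication:
    subject: str  # drug or drug-class name
    kind: str  # drug_disease | drug_drug | drug_food
    object: str
    note: str = ""


@dataclass
class PlanTemplate:
    template_id: str
    tier: str
    component_classes: tuple[str, ...]
    characteristics: Optional[ClassCharacteristics] = None


@dataclass
class KnowledgeBase:
    schema_version: int
    vocabulary: dict[str, dict[str, dict]]  # section -> code -> entry
    disease_parents: dict[str, tuple[str, ...]]
    drug_classes: dict[str, DrugClass]
    drugs: dict[str, Drug]
    contraindications: list[Contraindication]
    templates: list[PlanTemplate]
    rules: list[dict]
    diet: dict
    thresholds: dict
    targets: dict
    class_priority: list[str]
    preference_weights: dict[str, float]
    exercise: dict
    education: dict
    raw: dict = field(repr=False, default_factory=dict)

    # -- taxonomy helpers ---------------------------------------------------

    def drug(self, name: str) -> Drug:
        try:
            return self.drugs[name]
        except KeyError:
            raise UnresolvedCodeError(f"unknown drug {name!r}") from None

    def class_ancestors(self, name: str) -> tuple[str, ...]:
        """Reflexive-transitive class ancestry, most specific first."""
        if name not in self.drug_classes:
            raise UnresolvedCodeError(f"unknown drug class {name!r}")
        chain = [name]
        while self.drug_classes[chain[-1]].parent:
            chain.append(self.drug_classes[chain[-1]].parent)
        return tuple(chain)

    def class_descendants(self, name: str) -> tuple[str, ...]:
        if name not in self.drug_classes:
            raise UnresolvedCodeError(f"unknown drug class {name!r}")
        return tuple(
            c for c in self.drug_classes if name in self.class_ancestors(c)
        )

    def diabetes_classes(self) -> list[str]:
        """The top-level (parentless) diabetes drug classes."""
        return [
            c.name
            for c in self.drug_classes.values()
            if c.diabetes and c.parent is None
        ]

    def drugs_in_class(self, class_name: str) -> list[Drug]:
        members = self.class_descendants(class_name)
        return [d for d in self.drugs.values() if d.drug_class in members]

    def mechanism_of(self, class_name: str) -> str:
        return self.drug_classes[class_name].mechanism_of_action

    def disease_ancestors(self, code: str) -> tuple[str, ...]:
        """Reflexive-transitive disease subsumption closure."""
        seen: list[str] = []
        frontier = [code]
        while frontier:
            current = frontier.pop()
            if current in seen:
                continue
            seen.append(current)
            frontier.extend(self.disease_parents.get(current, ()))
        return tuple(seen)

    def resolve_record(self, record: ClinicalRecord) -> None:
        """Resolve a clinical record's code against the vocabulary; flags
        diabetes symptoms.  Medications resolve against the drug roster."""
        if record.kind == "symptom":
            entry = self.vocabulary["symptoms"].get(record.code)
            if entry is None:
                raise UnknownCodeError(f"unknown symptom code {record.code!r}")
            record.is_diabetes_symptom = bool(entry.get("is_diabetes_symptom"))
        elif record.kind == "disease":
            if record.code not in self.vocabulary["diseases"]:
                raise UnknownCodeError(f"unknown disease code {record.code!r}")
        elif record.kind == "medication":
            if record.code not in self.drugs:
                raise UnknownCodeError(f"unknown medication code {record.code!r}")

    def template(self, template_id: str) -> PlanTemplate:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise UnresolvedCodeError(f"unknown template {template_id!r}")


# ---------------------------------------------------------------------------
# loading


def default_kb_path() -> Path:
    return Path(importlib.resources.files("diaplan") / "data" / "default_kb.yaml")


_DEFAULT_KB_CACHE: Optional[KnowledgeBase] = None


def default_kb() -> KnowledgeBase:
    """The bundled knowledge base (cached)."""
    global _DEFAULT_KB_CACHE
    if _DEFAULT_KB_CACHE is None:
        _DEFAULT_KB_CACHE = load_kb(default_kb_path())
    return _DEFAULT_KB_CACHE


def _parse_characteristics(doc: Optional[dict], where: str):
    if doc is None:
        return None
    ch = ClassCharacteristics(
        efficiency=doc["efficiency"],
        hypoglycemic_risk=doc["hypoglycemic_risk"],
        weight_effect=doc["weight_effect"],
        side_effects=tuple(doc.get("side_effects", ())),
        cost=doc["cost"],
    )
    ch.validate(where)
    return ch


def load_kb(document: Union[str, Path, dict, None] = None) -> KnowledgeBase:
    """Load, cross-reference, and validate a knowledge-base document.

    ``document`` may be a YAML path, an already-parsed dict, or ``None`` for
    the bundled default.
    """
    if document is None:
        document = default_kb_path()
    if isinstance(document, (str, Path)):
        raw = yaml.safe_load(Path(document).read_text())
    else:
        raw = document
    if not isinstance(raw, dict):
        raise KBConflictError("KB document must be a mapping")

    vocabulary: dict[str, dict[str, dict]] = {}
    disease_parents: dict[str, tuple[str, ...]] = {}
    for section in ("diseases", "symptoms", "foods"):
        entries = raw.get("vocabulary", {}).get(section, [])
        table: dict[str, dict] = {}
        for entry in entries:
            if isinstance(entry, str):
                entry = {"code": entry}
            code = entry["code"]
            if code in table:
                raise KBConflictError(f"duplicate {section} code {code!r}")
            table[code] = entry
            if section == "diseases" and entry.get("is_a"):
                disease_parents[code] = tuple(entry["is_a"])
        vocabulary[section] = table
    for child, parents in disease_parents.items():
        for parent in parents:
            if parent not in vocabulary["diseases"]:
                raise UnresolvedCodeError(
                    f"disease {child!r} declares unknown parent {parent!r}"
                )

    drug_classes: dict[str, DrugClass] = {}
    for doc in raw.get("drug_classes", []):
        name = doc["name"]
        if name in drug_classes:
            raise KBConflictError(f"duplicate drug class {name!r}")
        moa = doc.get("mechanism_of_action", "")
        if doc.get("diabetes") and not moa:
            raise KBConflictError(f"diabetes class {name!r} lacks mechanism_of_action")
        drug_classes[name] = DrugClass(
            name=name,
            mechanism_of_action=moa,
            diabetes=bool(doc.get("diabetes", False)),
            parent=doc.get("parent"),
            characteristics=_parse_characteristics(
                doc.get("characteristics"), f"class {name}"
            ),
        )
    for cls in drug_classes.values():
        if cls.parent is not None and cls.parent not in drug_classes:
            raise UnresolvedCodeError(
                f"class {cls.name!r} has unknown parent {cls.parent!r}"
            )
        if cls.parent is not None and drug_classes[cls.parent].diabetes:
            cls.diabetes = True

    drugs: dict[str, Drug] = {}
    for doc in raw.get("drugs", []):
        name = doc["name"]
        if name in drugs:
            raise KBConflictError(f"duplicate drug {name!r}")
        if doc["drug_class"] not in drug_classes:
            raise UnresolvedCodeError(
                f"drug {name!r} references unknown class {doc['drug_class']!r}"
            )
        max_dose = float(doc.get("max_dose_per_day", 0) or 0)
        if "max_dose_per_day" in doc and max_dose <= 0:
            raise KBConflictError(f"drug {name!r}: max_dose_per_day must be > 0")
        drugs[name] = Drug(
            name=name,
            drug_class=doc["drug_class"],
            max_dose_per_day=max_dose,
            dose_unit=doc.get("dose_unit", "mg"),
            start_dose=doc.get("start_dose"),
            dose_step=doc.get("dose_step"),
            dose_form=doc.get("dose_form", "tablet"),
            route=doc.get("route", "oral"),
            times_per_day=int(doc.get("times_per_day", 1)),
            cost=doc.get("cost", "low"),
            a1c_lowering=doc.get("a1c_lowering"),
            is_diabetes_drug=bool(drug_classes[doc["drug_class"]].diabetes),
        )

    kb = KnowledgeBase(
        schema_version=int(raw.get("schema_version", 1)),
        vocabulary=vocabulary,
        disease_parents=disease_parents,
        drug_classes=drug_classes,
        drugs=drugs,
        contraindications=[],
        templates=[],
        rules=list(raw.get("rules", [])),
        diet=dict(raw.get("diet", {})),
        thresholds=dict(raw.get("thresholds", {})),
        targets=dict(raw.get("targets", {})),
        class_priority=list(raw.get("class_priority", [])),
        preference_weights=dict(
            raw.get("preference_weights")
            or {"efficiency": 1.0, "hypoglycemic_risk": 1.0,
                "weight_effect": 1.0, "cost": 1.0}
        ),
        exercise=dict(raw.get("exercise", {})),
        education=dict(raw.get("education", {})),
        raw=raw,
    )

    for doc in raw.get("contraindications", []):
        subject, kind, obj = doc["subject"], doc["kind"], doc["object"]
        if subject not in drugs and subject not in drug_classes:
            raise UnresolvedCodeError(
                f"contraindication subject {subject!r} is not a known drug or class"
            )
        registry = {
            "drug_disease": vocabulary["diseases"],
            "drug_drug": drugs,
            "drug_food": vocabulary["foods"],
        }
        if kind not in registry:
            raise KBConflictError(f"unknown contraindication kind {kind!r}")
        if obj not in registry[kind]:
            raise UnresolvedCodeError(
                f"contraindication object {obj!r} unresolved for kind {kind!r}"
            )
        kb.contraindications.append(
            Contraindication(subject=subject, kind=kind, object=obj,
                             note=doc.get("note", ""))
        )

    kb.templates = _expand_templates(raw.get("plan_templates", {}), kb)

    for name in kb.class_priority:
        if name not in drug_classes:
            raise UnresolvedCodeError(f"class_priority lists unknown class {name!r}")

    from .rule_engine import lint_rules  # deferred: avoids import cycle

    lint_rules(kb.rules)
    return kb


def _check_template_components(template_id, components, kb):
    if len(set(components)) != len(components):
        raise KBConflictError(f"{template_id}: duplicate component class")
    moas = []
    for cls in components:
        if cls not in kb.drug_classes:
            raise UnresolvedCodeError(
                f"{template_id}: unknown component class {cls!r}"
            )
        moas.append(kb.mechanism_of(cls))
    if len(set(moas)) != len(moas):
        raise KBConflictError(
            f"{template_id}: two component classes share a mechanism of action"
        )


def _expand_templates(doc: dict, kb: KnowledgeBase) -> list[PlanTemplate]:
    templates: list[PlanTemplate] = []
    seen: set[str] = set()

    def add(template: PlanTemplate) -> None:
        if template.template_id in seen:
            raise KBConflictError(f"duplicate template id {template.template_id!r}")
        seen.add(template.template_id)
        _check_template_components(
            template.template_id, template.component_classes, kb
        )
        templates.append(template)

    add(PlanTemplate("IP", "initial", ()))
    base_class = doc.get("monotherapy", {}).get("base_class", "biguanide")
    add(PlanTemplate("MP", "mono", (base_class,)))

    dual_by_id: dict[str, PlanTemplate] = {}
    for entry in doc.get("dual", []):
        template = PlanTemplate(
            entry["id"],
            "dual",
            (base_class, entry["added"]),
            characteristics=_parse_characteristics(
                entry.get("characteristics"), entry["id"]
            ),
        )
        add(template)
        dual_by_id[entry["id"]] = template

    for entry in doc.get("triple", []):
        base = dual_by_id.get(entry["base"])
        if base is None:
            raise UnresolvedCodeError(
                f"{entry['id']}: unknown dual base {entry['base']!r}"
            )
        for letter, option in zip("abcdefghij", entry["options"]):
            add(
                PlanTemplate(
                    f"{entry['id']}-{letter}",
                    "triple",
                    base.component_classes + (option,),
                )
            )

    for entry in doc.get("injectable", []):
        add(PlanTemplate(entry["id"], "injectable", tuple(entry["components"])))
    return templates


def write_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    """Write the KB back to YAML with stable key ordering."""
    Path(path).write_text(
        yaml.safe_dump(kb.raw, sort_keys=False, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# queries over the KB


def contraindications_for(
    profile: PatientProfile, target: str, kb: KnowledgeBase
) -> list[Contraindication]:
    """Contraindication records matching a profile for a drug or drug class.

    A record matches when its object is a disease the patient has (including
    super-diseases via the KB subsumption edges) or a medication the patient
    takes.  A class-level query aggregates over the class, its ancestors and
    descendants, and all member drugs; a drug-level query covers the drug and
    its class ancestry.
    """
    if target in kb.drugs:
        subjects = {target, *kb.class_ancestors(kb.drugs[target].drug_class)}
    elif target in kb.drug_classes:
        subjects = {
            *kb.class_ancestors(target),
            *kb.class_descendants(target),
            *(d.name for d in kb.drugs_in_class(target)),
        }
    else:
        raise UnresolvedCodeError(f"unknown drug or class {target!r}")

    disease_closure: set[str] = set()
    for code in profile.diseases:
        disease_closure.update(kb.disease_ancestors(code))
    meds = set(profile.medications)

    hits = []
    for ci in kb.contraindications:
        if ci.subject not in subjects:
            continue
        if ci.kind == "drug_disease" and ci.object in disease_closure:
            hits.append(ci)
        elif ci.kind == "drug_drug" and ci.object in meds:
            hits.append(ci)
        # drug_food records never match: profiles carry no food intake records
    return hits


def enumerate_medication_plans(
    kb: KnowledgeBase, tier: Optional[str] = None
) -> list[PlanTemplate]:
    """All medication-bearing plan templates (every tier except initial),
    optionally filtered to one tier, in deterministic load order."""
    if tier is not None and tier not in TIER_ORDER:
        raise UnresolvedCodeError(f"unknown tier {tier!r}")
    return [
        t
        for t in kb.templates
        if t.tier != "initial" and (tier is None or t.tier == tier)
    ]


# ---------------------------------------------------------------------------
# competency-question queries over a cohort

SUPPORTED_QUERIES = ("achieved_goals", "taking_drug", "diagnosed_untreated",
                     "has_disease")


def query_cohort(
    patients: Iterable[Patient],
    question: str,
    parameter: Optional[str] = None,
    kb: Optional[KnowledgeBase] = None,
) -> list[str]:
    """Answer a competency question over a cohort; returns patient ids.

    Selectors: ``achieved_goals`` (a plan reached its target after the review
    window), ``taking_drug`` (active plan prescribes drug X),
    ``diagnosed_untreated`` (diagnosed with T2DM, no previous plan),
    ``has_disease`` (any profile records disease X, honouring subsumption when
    a KB is supplied).
    """
    if question not in SUPPORTED_QUERIES:
        raise UnsupportedQueryError(f"unsupported query {question!r}")
    review_months = (kb.thresholds.get("review_months", 3) if kb else 3)
    ids = []
    for patient in patients:
        if _matches(patient, question, parameter, kb, review_months):
            ids.append(patient.patient_id)
    return ids


def _matches(patient, question, parameter, kb, review_months) -> bool:
    if question == "achieved_goals":
        return any(
            plan.status == "target_achieved"
            and plan.months_elapsed >= review_months
            for plan in patient.plans
        )
    if question == "taking_drug":
        if parameter is None:
            raise UnsupportedQueryError("taking_drug requires a drug name")
        plan = patient.active_plan
        return plan is not None and any(
            p.drug == parameter for p in plan.drug_subplan.prescriptions
        )
    if question == "diagnosed_untreated":
        profile = patient.latest_profile
        diagnosed = "diagnosis:t2dm" in profile.derived
        if not diagnosed and kb is not None:
            from .rule_engine import evaluate

            facts = evaluate(profile, kb)
            diagnosed = facts.has("has_diagnosis", profile.patient_id, "t2dm")
        return diagnosed and not profile.has_previous_treatment_plan and not patient.plans
    if question == "has_disease":
        if parameter is None:
            raise UnsupportedQueryError("has_disease requires a disease code")
        for profile in patient.profiles:
            for code in profile.diseases:
                ancestry = kb.disease_ancestors(code) if kb else (code,)
                if parameter in ancestry:
                    return True
        return False
    raise UnsupportedQueryError(question)
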