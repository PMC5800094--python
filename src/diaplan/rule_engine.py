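"""Stratified forward chaining over conjunctive Horn rules.

Rules are grouped into four phases executed in a fixed clinical order:

* **PER** — patient evaluation (symptomatic/asymptomatic, adult, …)
* **PDR** — diagnosis from lab results (T2DM, prediabetes, severe case)
* **PCR** — interaction checking (drug–disease, drug–drug contraindications)
* **PTR** — treatment suggestions (candidate drug classes, insulin flags)

Each phase runs to a least fixpoint with semi-naive evaluation; facts only ever
accumulate (monotone, so the fixpoint is order-independent), and the evaluation
terminates because rules are *safe* — every variable in a consequent, builtin,
or guard atom is bound by a positive antecedent atom, and there are no function
symbols, so the Herbrand universe is the finite constant set.

Negation is deliberately not available inside a phase.  A rule may carry
``unless`` guard atoms; these are absence tests evaluated against the snapshot
of facts *at phase entry*, which keeps every phase monotone while letting PTR
rules condition on "no PCR contraindication was derived".
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, Sequence

from .errors import UnsafeRuleError
from .knowledge_base import KnowledgeBase
from .profile_model import PatientProfile

PHASES = ("PER", "PDR", "PCR", "PTR")

BUILTINS = {
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
    "eq": operator.eq,
    "ne": operator.ne,
}

Term = Any  # constants (str/int/float) or variable strings starting with "?"


def is_variable(term: Term) -> bool:
    return isinstance(term, str) and term.startswith("?")


@dataclass(frozen=True)
class Atom:
    predicate: str
    args: tuple[Term, ...]

    @property
    def is_builtin(self) -> bool:
        return self.predicate in BUILTINS

    def variables(self) -> set[str]:
        return {a for a in self.args if is_variable(a)}

    def substitute(self, binding: dict[str, Term]) -> "Atom":
        return Atom(self.predicate,
                    tuple(binding.get(a, a) if is_variable(a) else a
                          for a in self.args))

    @classmethod
    def parse(cls, raw: Sequence) -> "Atom":
        return cls(str(raw[0]), tuple(raw[1:]))

    def as_list(self) -> list:
        return [self.predicate, *self.args]


@dataclass
class Rule:
    rule_id: str
    phase: str
    antecedent: tuple[Atom, ...]
    consequent: tuple[Atom, ...]
    unless: tuple[Atom, ...] = ()

    @classmethod
    def parse(cls, doc: dict) -> "Rule":
        return cls(
            rule_id=str(doc["id"]),
            phase=str(doc["phase"]),
            antecedent=tuple(Atom.parse(a) for a in doc.get("if", [])),
            consequent=tuple(Atom.parse(a) for a in doc.get("then", [])),
            unless=tuple(Atom.parse(a) for a in doc.get("unless", [])),
        )

    def check_safety(self) -> None:
        bound = set()
        for atom in self.antecedent:
            if not atom.is_builtin:
                bound |= atom.variables()
        unsafe = set()
        for atom in self.antecedent:
            if atom.is_builtin:
                unsafe |= atom.variables() - bound
        for atom in self.consequent + self.unless:
            unsafe |= atom.variables() - bound
        if unsafe:
            raise UnsafeRuleError(
                f"rule {self.rule_id!r}: variables {sorted(unsafe)} not bound "
                "by a positive antecedent atom"
            )
        if self.phase not in PHASES:
            raise UnsafeRuleError(
                f"rule {self.rule_id!r}: unknown phase {self.phase!r}"
            )
        for atom in self.antecedent:
            if atom.is_builtin and len(atom.args) != 2:
                raise UnsafeRuleError(
                    f"rule {self.rule_id!r}: builtin {atom.predicate} needs "
                    "exactly two operands"
                )


def lint_rules(rule_docs: Iterable[dict]) -> list[Rule]:
    """Parse and safety-check a rule list; raises :class:`UnsafeRuleError`."""
    rules = [Rule.parse(doc) for doc in rule_docs]
    seen = set()
    for rule in rules:
        if rule.rule_id in seen:
            raise UnsafeRuleError(f"duplicate rule id {rule.rule_id!r}")
        seen.add(rule.rule_id)
        rule.check_safety()
    return rules


@dataclass
class FactBase:
    """A monotonically growing set of ground atoms with provenance.

    ``provenance`` maps each fact to ``("asserted", ())`` or to the rule id
    and premise facts that produced it, enabling explanation chains.
    """

    facts: set[Atom] = field(default_factory=set)
    provenance: dict[Atom, tuple[str, tuple[Atom, ...]]] = field(
        default_factory=dict
    )

    def assert_fact(self, atom: Atom, rule_id: str = "asserted",
                    premises: tuple[Atom, ...] = ()) -> bool:
        if atom in self.facts:
            return False
        self.facts.add(atom)
        self.provenance[atom] = (rule_id, premises)
        return True

    def has(self, predicate: str, *args: Term) -> bool:
        return Atom(predicate, args) in self.facts

    def matching(self, predicate: str, arity: Optional[int] = None) -> list[Atom]:
        return sorted(
            (f for f in self.facts
             if f.predicate == predicate
             and (arity is None or len(f.args) == arity)),
            key=lambda f: tuple(map(str, f.args)),
        )

    def copy(self) -> "FactBase":
        return FactBase(set(self.facts), dict(self.provenance))

    def explain(self, atom: Atom, _depth: int = 0) -> list[str]:
        """Indented textual derivation chain for one fact."""
        rule_id, premises = self.provenance.get(atom, ("unknown", ()))
        lines = [f"{'  ' * _depth}{atom.as_list()}  <- {rule_id}"]
        for premise in premises:
            lines.extend(self.explain(premise, _depth + 1))
        return lines

    def explanation_dict(self, atom: Atom) -> dict:
        rule_id, premises = self.provenance.get(atom, ("unknown", ()))
        return {
            "fact": atom.as_list(),
            "rule": rule_id,
            "premises": [self.explanation_dict(p) for p in premises],
        }


# ---------------------------------------------------------------------------
# grounding a profile


def profile_to_facts(profile: PatientProfile, kb: KnowledgeBase) -> FactBase:
    """Ground a profile plus the KB constants into an initial fact base."""
    fb = FactBase()
    p = profile.patient_id
    d = profile.demographics
    for atom in (
        Atom("has_age", (p, d.age)),
        Atom("has_sex", (p, d.sex)),
        Atom("has_height", (p, float(d.height_cm))),
        Atom("has_weight", (p, float(d.weight_kg))),
        Atom("has_social_state", (p, d.social_state)),
        Atom("has_activity_level", (p, d.activity_level)),
        Atom("has_language", (p, d.language)),
        Atom("has_education_level", (p, d.education_level)),
    ):
        fb.assert_fact(atom)

    for lab in profile.labs:
        fb.assert_fact(
            Atom("has_lab", (p, lab.test, float(lab.value), lab.date.isoformat()))
        )
    for rec in profile.records:
        predicate = {
            "symptom": "has_symptom",
            "disease": "has_complication",
            "medication": "takes_drug",
        }[rec.kind]
        fb.assert_fact(Atom(predicate, (p, rec.code)))

    n_diabetes_symptoms = sum(1 for r in profile.records if r.is_diabetes_symptom)
    fb.assert_fact(Atom("diabetes_symptom_count", (p, n_diabetes_symptoms)))
    if profile.has_previous_treatment_plan:
        fb.assert_fact(Atom("has_previous_plan", (p,)))
    else:
        fb.assert_fact(Atom("no_previous_plan", (p,)))

    # KB constants: disease subsumption closure and the contraindication registry
    for disease in kb.vocabulary["diseases"]:
        for ancestor in kb.disease_ancestors(disease):
            fb.assert_fact(Atom("disease_subtype_of", (disease, ancestor)))
    for ci in kb.contraindications:
        if ci.kind == "drug_disease":
            fb.assert_fact(Atom("contraindication_disease", (ci.subject, ci.object)))
        elif ci.kind == "drug_drug":
            fb.assert_fact(Atom("contraindication_drug", (ci.subject, ci.object)))
    for drug in kb.drugs.values():
        for cls in kb.class_ancestors(drug.drug_class):
            fb.assert_fact(Atom("drug_in_class", (drug.name, cls)))
    return fb


# ---------------------------------------------------------------------------
# evaluation


def _match(
    atoms: Sequence[Atom],
    index: int,
    binding: dict[str, Term],
    facts: set[Atom],
    by_predicate: dict[tuple[str, int], list[Atom]],
    delta: Optional[set[Atom]],
    used_delta: bool,
) -> Iterator[tuple[dict[str, Term], tuple[Atom, ...], bool]]:
    """Backtracking join over the antecedent; yields full bindings together
    with the premise facts used.  When ``delta`` is given, only bindings that
    touch at least one delta fact are yielded (semi-naive restriction)."""
    if index == len(atoms):
        if delta is None or used_delta:
            yield binding, (), True
        return
    atom = atoms[index]
    if atom.is_builtin:
        ground = atom.substitute(binding)
        if any(is_variable(a) for a in ground.args):  # unreachable for safe rules
            return
        try:
            ok = BUILTINS[atom.predicate](ground.args[0], ground.args[1])
        except TypeError:
            ok = False
        if ok:
            for result in _match(atoms, index + 1, binding, facts,
                                 by_predicate, delta, used_delta):
                yield result
        return
    for fact in by_predicate.get((atom.predicate, len(atom.args)), ()):
        trial = dict(binding)
        if _unify(atom, fact, trial):
            hit_delta = used_delta or (delta is not None and fact in delta)
            for bound, premises, _ in _match(atoms, index + 1, trial, facts,
                                             by_predicate, delta, hit_delta):
                yield bound, (fact,) + premises, True


def _unify(pattern: Atom, fact: Atom, binding: dict[str, Term]) -> bool:
    for pat, val in zip(pattern.args, fact.args):
        if is_variable(pat):
            if pat in binding:
                if binding[pat] != val:
                    return False
            else:
                binding[pat] = val
        elif pat != val:
            return False
    return True


def _index(facts: Iterable[Atom]) -> dict[tuple[str, int], list[Atom]]:
    table: dict[tuple[str, int], list[Atom]] = {}
    for fact in facts:
        table.setdefault((fact.predicate, len(fact.args)), []).append(fact)
    return table


def fire_phase(facts: FactBase, rules: Sequence[Rule], phase: str) -> FactBase:
    """Run one phase's rules to their least fixpoint (semi-naive).

    Guards (``unless`` atoms) are tested against the facts present when the
    phase started, so conclusions of the running phase can never retract an
    already-enabled rule — the phase stays monotone.
    """
    phase_rules = [r for r in rules if r.phase == phase]
    result = facts.copy()
    snapshot = frozenset(facts.facts)
    delta: Optional[set[Atom]] = None  # first round: consider everything
    while True:
        new: list[tuple[Atom, str, tuple[Atom, ...]]] = []
        index = _index(result.facts)
        for rule in phase_rules:
            for binding, premises, _ in _match(
                rule.antecedent, 0, {}, result.facts, index, delta, False
            ):
                if any(g.substitute(binding) in snapshot for g in rule.unless):
                    continue
                for template in rule.consequent:
                    ground = template.substitute(binding)
                    if ground not in result.facts:
                        new.append((ground, rule.rule_id, premises))
        added = set()
        for ground, rule_id, premises in new:
            if result.assert_fact(ground, rule_id, premises):
                added.add(ground)
        if not added:
            return result
        delta = added


def evaluate(
    profile: PatientProfile,
    kb: KnowledgeBase,
    rules: Optional[Sequence[Rule]] = None,
) -> FactBase:
    """Full stratified evaluation: PER → PDR → PCR → PTR.

    Each phase sees all earlier conclusions.  Derived facts about the patient
    are mirrored into ``profile.derived`` for downstream components.
    """
    if rules is None:
        rules = lint_rules(kb.rules)
    facts = profile_to_facts(profile, kb)
    for phase in PHASES:
        facts = fire_phase(facts, rules, phase)
    _record_derived(profile, facts)
    return facts


def _record_derived(profile: PatientProfile, facts: FactBase) -> None:
    p = profile.patient_id
    for tag, predicate in (
        ("symptomatic", "symptomatic"),
        ("adult", "adult"),
        ("severe_case", "severe_case"),
        ("insulin_combination", "consider_insulin_combination"),
    ):
        if facts.has(predicate, p):
            profile.derived.add(tag)
    for fact in facts.matching("has_diagnosis", 2):
        if fact.args[0] == p:
            profile.derived.add(f"diagnosis:{fact.args[1]}")
    for fact in facts.matching("contraindicated", 2):
        if fact.args[0] == p:
            profile.derived.add(f"contraindicated:{fact.args[1]}")
    for fact in facts.matching("suggested_class", 2):
        if fact.args[0] == p:
            profile.derived.add(f"suggested_class:{fact.args[1]}")
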