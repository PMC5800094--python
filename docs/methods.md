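# Methods

This note documents the models, parameters, numerical choices, and design
decisions behind `diaplan`, and what the synthetic-data tests do and do not
establish about real clinical data.

## The planning model

A patient is a time-ordered sequence of profiles (demographics, lab results,
symptom/disease/medication records, a previous-plan flag). Planning is a
pure function of one profile and the knowledge base (KB): the engine never
consults external state, so every run is reproducible from its inputs.

### Rule engine

Rules are safe conjunctive Horn clauses over ground atoms, with binary
numeric comparison builtins (`lt le gt ge eq ne`), organised into four
strata executed in a fixed clinical order: patient evaluation (PER),
diagnosis (PDR), interaction checking (PCR), treatment suggestion (PTR).
Each stratum runs to its least fixpoint with semi-naive evaluation. Because
rules are monotone and function-free over a finite constant universe, the
fixpoint exists, is unique (hence independent of rule ordering), and is
reached in finitely many rounds; the test suite checks agreement with a
naive full-grounding oracle on randomized programs.

Negation is not available inside a stratum. Absence conditions ("no
contraindication was derived") are `unless` guards resolved against the
facts present when the stratum *starts* — i.e. against fully-closed earlier
strata — which preserves monotonicity and determinism. Tie-breaking among
competing treatment suggestions is deliberately *not* a rule-engine concern:
PTR emits all eligible classes as facts and the plan generator selects.

Numeric builtins compare values in their declared units; no unit conversion
happens inside rules (the profile loader enforces HbA1c in % and glucose in
mg/dL at ingestion, so rule thresholds are unambiguous).

Provenance (fact → producing rule → premise facts) is kept for every
derived atom and rendered as explanation chains in reports.

### Diagnosis thresholds

The bundled PDR rules use the standard ADA cut-points: T2DM at
HbA1c ≥ 6.5 % or FPG ≥ 126 mg/dL, or RPG ≥ 200 mg/dL in a symptomatic
patient; prediabetes at HbA1c 5.7–6.4 % or FPG 100–125 mg/dL. A *severe
case* (symptomatic with glucose ≥ 300 mg/dL or HbA1c ≥ 10 %) flags the plan
for injectable-insulin combination consideration. The severe-case
thresholds, the adult age threshold (strict > 45), and the three-month
review window are KB parameters (`thresholds:`), not code constants.

### Drug taxonomy and contraindications

The KB ships nine top-level diabetes drug classes (alpha-glucosidase
inhibitor, biguanide, dopamine agonist, incretin, insulin, meglitinide,
SGLT-2 inhibitor, sulfonylurea, thiazolidinedione), each with a
mechanism-of-action tag. DPP-4 inhibitors and GLP-1 receptor agonists are
subclasses of the incretin class and share its mechanism tag — which is
exactly why no template combines them. Basal and mealtime insulin are
subclasses of insulin with distinct supplementation mechanisms so the
injectable regimen may pair them.

Contraindication matching is by exact code plus KB-declared disease
subsumption edges evaluated transitively (e.g. nonparalytic stroke *is a*
cerebrovascular disease). A class-level contraindication covers all member
drugs; a drug-level query also inherits its class ancestry. Drug–food
records are representable in the KB but cannot match a profile (profiles
record symptoms, diseases, and medications only); they are retained for
completeness of the registry.

### Plan templates and escalation

Templates are stored generatively and expanded at load: one monotherapy
template (biguanide base), six dual combinations (base + one of
sulfonylurea, thiazolidinedione, DPP-4 inhibitor, SGLT-2 inhibitor, GLP-1
receptor agonist, basal insulin), six triple families whose option lists
expand to 25 concrete combinations, and two injectable regimens (basal +
mealtime insulin; basal insulin + GLP-1 receptor agonist) — 34 medication
plans. Load-time validation rejects duplicate classes or shared mechanisms
inside any expanded template.

Escalation is a one-way ladder `initial → mono → dual → triple →
injectable`, driven by three-month reviews:

* target achieved → renew the identical regimen for another period;
* target missed, any dose below maximum → titrate by the drug's KB-declared
  step, capped at its maximum daily dose;
* target missed at maximum dose → escalate one tier.

The escalation step considers the next tier's templates by their *added*
class (their last component), keeping the patient's current
non-contraindicated drugs. This mirrors the monotherapy substitution rule:
a patient whose regimen already deviates from the canonical templates
(because a class was substituted) still escalates along the same ladder,
and the chosen template id is marked with `*` when the resulting
combination is a substituted variant. Among eligible dual templates the
choice is ranked by the template characteristics table (efficiency ↑,
hypoglycemic risk ↓, weight effect toward loss, cost ↓; configurable
weights, lexicographic template-id tie-break). Triple templates prefer the
family whose base matches the current combination, then listed order. The
injectable tier replaces the oral stack, following the
"lifestyle + insulin-based" regimen design. This ranking is a package
design decision: the underlying guidance says only that the choice follows
the patient's condition, without an algorithm.

Drug selection inside a class filters by (1) no matching contraindication,
(2) affordability — a patient with social state `poor` is restricted to
low-cost drugs — then takes the first survivor in KB order. A consequence
worth knowing: a low-income patient can exhaust every affordable class at
a higher tier, in which case the planner raises *manual review required*
rather than prescribing an unaffordable or unsafe drug.

Defaults with no printed source, chosen once and configurable: target
HbA1c 7.0 %, fasting glucose 130 mg/dL, weight target = 0.95 × current
weight; a freshly diagnosed T2DM patient starts at monotherapy
(`start_tier="mono"`, matching the worked case) with `"initial"` available
for guideline variants that begin with lifestyle alone.

## Diet subplan

Harris–Benedict coefficients (kcal/24 h): male 66.47 + 13.75·W + 5.0·H −
6.75·A; female 665.09 + 9.56·W + 1.84·H − 4.67·A (W kg, H cm, A years).
Activity factors 1.2 / 1.375 / 1.55 / 1.725 / 1.9 for sedentary → extra
active. Meals split 25 / 12.5 / 25 / 12.5 / 25 %; nutrients 50 / 30 / 20 %
(carbohydrate / fat / protein); energy densities 4 / 9 / 4 kcal/g.

Numerical choices:

* Total calories are reported at 0.01 kcal resolution and all meal and
  nutrient splits start from that figure; this is the precision at which
  daily calorie prescriptions are stated and it makes the worked example's
  meal values exact. Downstream of TC everything is double precision and
  exactly conservative (meal kcal sum to TC; nutrient kcal sum to each
  meal) — property-tested over fuzzed demographics.
* Grams are rounded half-away-from-zero to whole grams; the rounding error
  is below 0.5 g per nutrient by construction. The unrounded kcal values
  are retained on the plan object.
* Narrative energy-fraction ranges (carbohydrate 50–60 %, fat 7–10 %) and
  ideal-body-weight protein dosing (1.0–1.2 g/kg) are stored as advisory
  KB metadata only; the operational 50/30/20 split is the computed one.
* Degenerate inputs: non-positive weight/height or BMR raise
  `InvalidAnthropometryError`; an unknown activity level raises
  `UnknownActivityLevelError`. The revised Harris–Benedict coefficient sets
  are not implemented — only the coefficient set above.

## Synthetic cohorts

The generator emulates a screening population, not an epidemiological one:
independent per-patient draws of demographics, per-symptom/disease/drug
prevalences (knob-controlled), and a two-component lab mixture
(normoglycemic vs hyperglycemic, default 50 % diabetic fraction so the
diagnosis rules fire on a controllable share). Patient *i* uses the
dedicated substream `(seed, i)`, so enlarging a cohort never perturbs
earlier patients. Follow-up simulation samples per-period target
achievement from a per-tier response model; on a failed period the regimen
is taken to have been titrated to maximum between visits, so persistent
failure escalates one tier per review (which is how the five-period
forced-failure trajectory walks initial → injectable).

What passing tests show — and what they do not: the generator produces
schema-valid, internally consistent profiles with controllable prevalences,
so the tests establish the *logic* (safety of prescriptions, conservation
of calories, order-invariance of inference, monotone escalation) over a
wide input space. They do not establish clinical validity on real
populations: correlations between comorbidities, medication histories,
longitudinal lab dynamics, adherence, and measurement error are all absent
by design. The bundled case fixture's lab values (HbA1c 8.1 %, FPG
190 mg/dL) are synthetic representative values chosen to be diagnostic but
non-severe.

## Known limitations

* The bundled rule set implements the documented behaviours (~20 rules);
  it is a faithful core, not an exhaustive guideline encoding, and is meant
  to be extended through the KB file.
* Insulin regimens are modeled only at the class level (basal/mealtime);
  titration of insulin doses is out of scope.
* No food-item database: diet plans are expressed in kcal and grams per
  macronutrient, not foods or exchange units.
* Treatment of diabetes complications (statins, antihypertensives, renal
  dosing) is limited to contraindication checking.
* Profile ingestion is plain JSON; no HL7/FHIR/openEHR connectivity.

## Problem sizes used in the shipped checks

The acceptance script audits a 1,000-patient seeded cohort and a
five-period forced-failure trajectory; the property suites fuzz 1,000
diet profiles, ~30 randomized rule programs, and a 4,000-patient
prevalence calibration. These sizes give tight binomial error bands
(three standard errors) while keeping the whole suite in seconds.
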