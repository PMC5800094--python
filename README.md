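# diaplan

Individualized treatment planning for type 2 diabetes mellitus (T2DM):
a declarative treatment knowledge base, a stratified forward-chaining rule
engine, a Harris–Benedict diet calculator, and a therapy-escalation state
machine that together turn a time-stamped patient profile into a complete,
explainable treatment plan.

The package is aimed at clinical-decision-support researchers and engineers
who want the planning logic of a computable T2DM guideline as an executable,
testable artifact — without a description-logic reasoner or an EHR
integration. All knowledge (drug taxonomy, contraindications, plan
templates, rules, thresholds) lives in one YAML document that can be
inspected, versioned, and replaced.

## What it computes

**Rule pipeline.** Facts grounded from a patient profile are closed under
four ordered groups of conjunctive Horn rules, each run to a least fixpoint:

1. **PER** (patient evaluation): e.g. *symptomatic* — at least three diabetes
   symptoms, or a cerebrovascular comorbidity; *adult* — age > 45.
2. **PDR** (diagnosis): T2DM when HbA1c ≥ 6.5 %, FPG ≥ 126 mg/dL, or
   symptomatic with RPG ≥ 200 mg/dL; *severe case* when symptomatic with
   glucose ≥ 300 mg/dL or HbA1c ≥ 10 %.
3. **PCR** (interaction checking): drug–disease and drug–drug
   contraindications, with disease subsumption (a nonparalytic stroke *is a*
   cerebrovascular disease).
4. **PTR** (treatment suggestion): candidate drug classes, with
   "no contraindication derived" expressed as cross-phase absence guards.

**Plans.** Medication templates span five tiers — initial (lifestyle +
education only), monotherapy (biguanide, substituting a non-contraindicated
class when needed), six dual combinations, twenty-five triple combinations,
and two injectable regimens: 34 medication plans in the bundled KB. No plan
may combine two drugs of one class or one mechanism of action. Every plan
carries a diet subplan, an exercise subplan (filtered by disease
contraindications), an education subplan (in the patient's language), and a
target reviewed after three months: achieved → renew; missed below maximum
dose → titrate; missed at maximum dose → escalate one tier.

**Diet subplan.** With weight W (kg), height H (cm), age A (years):

    BMR_male   = 66.47 + 13.75·W + 5.0·H − 6.75·A      (kcal/24 h)
    BMR_female = 665.09 + 9.56·W + 1.84·H − 4.67·A

Total calories TC = BMR × activity factor (1.2 … 1.9), split over five meals
at 25 / 12.5 / 25 / 12.5 / 25 %, each divided 50 / 30 / 20 % into
carbohydrate / fat / protein and converted to grams at 4 / 9 / 4 kcal per
gram (rounded half-up).

## Worked example

The bundled case patient is a 50-year-old male teacher, 100 kg, 180 cm,
light activity, low income, with lactic acidosis and a nonparalytic stroke
on record, taking dofetilide:

```bash
diaplan plan src/diaplan/data/case_study_profile.json
```

```
Treatment plan patient_1-plan-1 (2017-01-15)
  template MP  tier mono  status active

Diagnosis: t2dm
Contraindication audit: CLEAN

Prescriptions:
  glimepiride        1 mg tablet, oral, 1x/day, 3 months

Diet: BMR 2003.97 kcal/24h, total 2755.46 kcal/24h
  meal            kcal  carbohydrate g           fat g       protein g
  breakfast    688.865              86              23              34
  snack_1      344.433              43              11              17
  lunch        688.865              86              23              34
  snack_2      344.433              43              11              17
  dinner       688.865              86              23              34
...
Target: HbA1c <= 7.0%, FPG <= 130.0 mg/dL, weight 95.0 kg; review 2017-04-15
```

Reading the output: the rule engine found the patient symptomatic (the
stroke is a cerebrovascular disease) and adult, diagnosed T2DM from the
labs, and blocked the first-line biguanide class twice over (lactic
acidosis; dofetilide interaction). The monotherapy template was therefore
instantiated with glimepiride — a low-cost sulfonylurea this low-income
patient can afford — plus the diet shown (2003.97 kcal basal rate × 1.375
for light activity = 2755.46 kcal/day) and a three-month review target.
Add `--explain` to embed the full derivation chain of every conclusion.

Other subcommands: `diet`, `check` (contraindications only),
`enumerate-plans`, `generate` (synthetic cohorts), `simulate` (longitudinal
follow-ups), `query` (cohort competency questions), `lint-rules`,
`export-rdf`.

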