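"""Diet subplan arithmetic: Harris–Benedict BMR, activity-adjusted calories,
five-meal split, per-meal macronutrient calories and grams.

The pipeline is strictly deterministic:

1. BMR (kcal/24 h) from sex-specific Harris–Benedict coefficients,
2. total calories = BMR × activity factor (reported at 0.01 kcal resolution),
3. meal split 25 / 12.5 / 25 / 12.5 / 25 % over breakfast, snack 1, lunch,
   snack 2, dinner,
4. per-meal nutrient split 50 / 30 / 20 % (carbohydrate / fat / protein),
5. grams = nutrient kcal ÷ energy density (4, 9, 4 kcal/g), rounded half-up
   to whole grams; the unrounded kcal values are retained on the plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidAnthropometryError, UnknownActivityLevelError
from .profile_model import PatientProfile

MEAL_ORDER = ("breakfast", "snack_1", "lunch", "snack_2", "dinner")
NUTRIENT_ORDER = ("carbohydrate", "fat", "protein")


@dataclass
class DietParameters:
    # intercept, weight, height, age coefficients (kcal, kcal/kg, kcal/cm, kcal/y)
    bmr_coefficients: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "male": (66.47, 13.75, 5.0, 6.75),
            "female": (665.09, 9.56, 1.84, 4.67),
        }
    )
    activity_factors: dict[str, float] = field(
        default_factory=lambda: {
            "sedentary": 1.2,
            "light": 1.375,
            "moderate": 1.55,
            "very_active": 1.725,
            "extra_active": 1.9,
        }
    )
    meal_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "breakfast": 0.25,
            "snack_1": 0.125,
            "lunch": 0.25,
            "snack_2": 0.125,
            "dinner": 0.25,
        }
    )
    nutrient_fractions: dict[str, float] = field(
        default_factory=lambda: {"carbohydrate": 0.50, "fat": 0.30, "protein": 0.20}
    )
    kcal_per_gram: dict[str, float] = field(
        default_factory=lambda: {"carbohydrate": 4.0, "fat": 9.0, "protein": 4.0}
    )

    def validate(self) -> None:
        if abs(sum(self.meal_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("meal fractions must sum to 1")
        if abs(sum(self.nutrient_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("nutrient fractions must sum to 1")
        for table in (self.activity_factors, self.meal_fractions,
                      self.nutrient_fractions, self.kcal_per_gram):
            if any(v <= 0 for v in table.values()):
                raise ValueError("all diet factors must be strictly positive")

    @classmethod
    def from_kb(cls, kb) -> "DietParameters":
        doc = kb.diet if hasattr(kb, "diet") else dict(kb or {})
        params = cls()
        if "bmr_coefficients" in doc:
            params.bmr_coefficients = {
                sex: tuple(float(c) for c in coeffs)
                for sex, coeffs in doc["bmr_coefficients"].items()
            }
        for key in ("activity_factors", "meal_fractions", "nutrient_fractions",
                    "kcal_per_gram"):
            if key in doc:
                setattr(params, key, {k: float(v) for k, v in doc[key].items()})
        params.validate()
        return params


@dataclass
class Meal:
    name: str
    kcal: float
    nutrient_kcal: dict[str, float]
    nutrient_grams: dict[str, int]


@dataclass
class DietSubplan:
    bmr: float
    total_calories: float
    meals: list[Meal]

    def meal(self, name: str) -> Meal:
        for meal in self.meals:
            if meal.name == name:
                return meal
        raise KeyError(name)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def bmr(sex: str, weight_kg: float, height_cm: float, age_years: float,
        params: Optional[DietParameters] = None) -> float:
    """Basal metabolic rate in kcal/24 h (Harris–Benedict).

    male:   66.47 + 13.75·W + 5.0·H − 6.75·A
    female: 665.09 + 9.56·W + 1.84·H − 4.67·A
    """
    params = params or DietParameters()
    if weight_kg <= 0 or height_cm <= 0:
        raise InvalidAnthropometryError(
            f"weight and height must be positive, got {weight_kg}, {height_cm}"
        )
    if age_years < 0:
        raise InvalidAnthropometryError(f"age must be non-negative: {age_years}")
    try:
        intercept, w_coef, h_coef, a_coef = params.bmr_coefficients[sex]
    except KeyError:
        raise InvalidAnthropometryError(f"unknown sex {sex!r}") from None
    return intercept + w_coef * weight_kg + h_coef * height_cm - a_coef * age_years


def total_calories(bmr_value: float, activity_level: str,
                   params: Optional[DietParameters] = None) -> float:
    """Daily calorie requirement: BMR scaled by the activity factor.

    Reported at 0.01 kcal resolution, the precision at which daily calorie
    targets are stated; all downstream splits start from this figure.
    """
    params = params or DietParameters()
    if bmr_value <= 0:
        raise InvalidAnthropometryError(f"BMR must be positive: {bmr_value}")
    try:
        factor = params.activity_factors[activity_level]
    except KeyError:
        raise UnknownActivityLevelError(
            f"unknown activity level {activity_level!r}"
        ) from None
    return round(bmr_value * factor, 2)


def build_diet_subplan(profile: PatientProfile,
                       params: Optional[DietParameters] = None) -> DietSubplan:
    """Full diet subplan for one profile (see module docstring for stages)."""
    params = params or DietParameters()
    demo = profile.demographics
    bmr_value = bmr(demo.sex, demo.weight_kg, demo.height_cm, demo.age, params)
    tc = total_calories(bmr_value, demo.activity_level, params)

    meals = []
    for name in MEAL_ORDER:
        meal_kcal = tc * params.meal_fractions[name]
        nutrient_kcal = {
            nut: meal_kcal * params.nutrient_fractions[nut]
            for nut in NUTRIENT_ORDER
        }
        nutrient_grams = {
            nut: _round_half_up(kcal / params.kcal_per_gram[nut])
            for nut, kcal in nutrient_kcal.items()
        }
        meals.append(Meal(name, meal_kcal, nutrient_kcal, nutrient_grams))
    return DietSubplan(bmr=bmr_value, total_calories=tc, meals=meals)
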