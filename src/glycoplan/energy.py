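"""Daily energy requirements from anthropometrics.

Turns a user's personal details (sex, age, weight, height, activity level,
weight goal) into a daily calorie target and a BMI-based diet type:

* basal metabolic rate (BMR) from the revised Harris-Benedict equation
  (Roza & Shizgal 1984 coefficients),
* total daily energy expenditure = BMR x activity multiplier,
* a +/-500 kcal/day adjustment for a gain/lose goal,
* a 1200 kcal/day safety floor on the final target,
* WHO BMI classes (underweight / normal / overweight / obese) used as the
  diet type, each mapped to a default goal the user may override.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import IO, Union

from .errors import DomainError, ValidationError

SEXES = ("male", "female")
ACTIVITY_LEVELS = ("sedentary", "light", "moderate", "very_active", "extra_active")
GOALS = ("lose", "maintain", "gain")
DIET_TYPES = ("underweight", "normal", "overweight", "obese")

#: Revised Harris-Benedict coefficients (intercept, weight kg, height cm, age y).
HARRIS_BENEDICT_COEFFS = {
    "male": (88.362, 13.397, 4.799, -5.677),
    "female": (447.593, 9.247, 3.098, -4.330),
}

#: Standard dietetic activity multipliers applied to BMR.
ACTIVITY_MULTIPLIERS = {
    "sedentary": 1.2,
    "light": 1.375,
    "moderate": 1.55,
    "very_active": 1.725,
    "extra_active": 1.9,
}

#: kcal/day adjustment for the user's weight goal.
GOAL_ADJUSTMENTS = {"lose": -500.0, "maintain": 0.0, "gain": 500.0}

#: Safety floor on the daily target (kcal/day); prevents pathological
#: lose-weight targets for small or sedentary users.
MIN_DAILY_CALORIES = 1200.0

#: WHO BMI cutpoints (kg/m^2); lower bound inclusive, upper exclusive.
BMI_CUTPOINTS = ((18.5, "underweight"), (25.0, "normal"), (30.0, "overweight"))

#: Default weight goal implied by each diet type (user's explicit goal wins).
DEFAULT_GOAL_BY_DIET_TYPE = {
    "underweight": "gain",
    "normal": "maintain",
    "overweight": "lose",
    "obese": "lose",
}


@dataclass(frozen=True)
class UserProfile:
    """Anthropometrics plus lifestyle, the source of all energy math.

    Parameters
    ----------
    id : opaque identifier.
    sex : ``"male"`` or ``"female"``.
    age : years, in (0, 130].
    weight : kilograms, in (0, 500].
    height : centimetres, in (30, 280].
    activity_level : one of :data:`ACTIVITY_LEVELS`.
    goal : one of :data:`GOALS`.
    """

    id: str
    sex: str
    age: float
    weight: float
    height: float
    activity_level: str
    goal: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.activity_level not in ACTIVITY_LEVELS:
            raise DomainError(
                f"unknown activity_level {self.activity_level!r}; "
                f"expected one of {ACTIVITY_LEVELS}"
            )
        if self.goal not in GOALS:
            raise DomainError(f"unknown goal {self.goal!r}; expected one of {GOALS}")
        if not 0 < self.age <= 130:
            raise DomainError(f"age {self.age} outside (0, 130]")
        if not 0 < self.weight <= 500:
            raise DomainError(f"weight {self.weight} kg outside (0, 500]")
        if not 30 < self.height <= 280:
            raise DomainError(f"height {self.height} cm outside (30, 280]")


@dataclass(frozen=True)
class EnergyRequirement:
    """The computed daily energy picture for one profile."""

    bmr: float  # kcal/day at rest
    activity_multiplier: float
    goal_adjustment: float  # kcal/day
    daily_target: float  # kcal/day, >= MIN_DAILY_CALORIES
    bmi: float  # kg/m^2
    diet_type: str

    def to_dict(self) -> dict:
        return asdict(self)


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index in kg/m^2 from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise DomainError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def compute_bmr(profile: UserProfile) -> float:
    """Basal metabolic rate (kcal/day), revised Harris-Benedict equation."""
    intercept, cw, ch, ca = HARRIS_BENEDICT_COEFFS[profile.sex]
    return intercept + cw * profile.weight + ch * profile.height + ca * profile.age


def daily_calorie_target(
    bmr: float,
    activity_level: str,
    goal: str,
    *,
    floor: float = MIN_DAILY_CALORIES,
) -> float:
    """Total daily target: BMR x activity multiplier + goal adjustment.

    Clamped below at `floor` kcal/day.
    """
    if bmr <= 0:
        raise DomainError("bmr must be positive")
    try:
        multiplier = ACTIVITY_MULTIPLIERS[activity_level]
    except KeyError:
        raise DomainError(f"unknown activity level {activity_level!r}") from None
    try:
        adjustment = GOAL_ADJUSTMENTS[goal]
    except KeyError:
        raise DomainError(f"unknown goal {goal!r}") from None
    return max(floor, bmr * multiplier + adjustment)


def classify_diet_type(profile: UserProfile) -> tuple[str, str]:
    """WHO BMI class for the profile, plus the default goal it implies.

    Returns ``(diet_type, default_goal)``.  The default goal is advisory:
    the user's explicit ``profile.goal`` always takes precedence in
    :func:`energy_requirement`.
    """
    bmi = compute_bmi(profile.weight, profile.height)
    diet_type = diet_type_for_bmi(bmi)
    return diet_type, DEFAULT_GOAL_BY_DIET_TYPE[diet_type]


def diet_type_for_bmi(bmi: float) -> str:
    """Map a BMI value onto the WHO class; lower bound inclusive."""
    for upper, name in BMI_CUTPOINTS:
        if bmi < upper:
            return name
    return "obese"


def energy_requirement(profile: UserProfile) -> EnergyRequirement:
    """Full pipeline: BMR, target, BMI and diet type for one profile."""
    bmr = compute_bmr(profile)
    target = daily_calorie_target(bmr, profile.activity_level, profile.goal)
    bmi = compute_bmi(profile.weight, profile.height)
    return EnergyRequirement(
        bmr=bmr,
        activity_multiplier=ACTIVITY_MULTIPLIERS[profile.activity_level],
        goal_adjustment=GOAL_ADJUSTMENTS[profile.goal],
        daily_target=target,
        bmi=bmi,
        diet_type=diet_type_for_bmi(bmi),
    )


_PROFILE_FIELDS = {"id", "sex", "age", "weight", "height", "activity_level", "goal"}


def profile_from_dict(doc: dict) -> UserProfile:
    """Build a profile from a parsed JSON object, rejecting unknown keys."""
    if not isinstance(doc, dict):
        raise ValidationError("profile document must be a JSON object")
    missing = _PROFILE_FIELDS - doc.keys()
    if missing:
        raise ValidationError(f"profile missing fields: {sorted(missing)}")
    extra = doc.keys() - _PROFILE_FIELDS
    if extra:
        raise ValidationError(f"profile has unknown fields: {sorted(extra)}")
    try:
        return UserProfile(
            id=str(doc["id"]),
            sex=doc["sex"],
            age=float(doc["age"]),
            weight=float(doc["weight"]),
            height=float(doc["height"]),
            activity_level=doc["activity_level"],
            goal=doc["goal"],
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, DomainError):
            raise
        raise ValidationError(f"malformed profile: {exc}") from exc


def load_profile(source: Union[str, IO[str]]) -> UserProfile:
    """Read a UserProfile from a JSON file path or open text stream."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    return profile_from_dict(doc)
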