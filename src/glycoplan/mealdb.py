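"""The meal knowledge base the recommender searches.

A meal database is a JSON array of records, each with per-serving nutrition
(calories plus carbohydrate/protein/fat grams) and the meal slots it can fill
(breakfast, lunch, supper).  Loading enforces the Atwater consistency rule:
calories must agree with 4*carbs + 4*protein + 9*fat within 10% (hard error
above that; a warning is emitted above 2%, which covers honest rounding and
fibre effects in real food tables).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import IO, Union

from .errors import DomainError, ValidationError

SLOTS = ("breakfast", "lunch", "supper")

#: Atwater energy densities, kcal per gram.
ATWATER_KCAL_PER_G = {"carbs": 4.0, "protein": 4.0, "fat": 9.0}

#: Relative calorie deviation above which a record is rejected / warned about.
ATWATER_HARD_TOLERANCE = 0.10
ATWATER_WARN_TOLERANCE = 0.02

_MEAL_FIELDS = (
    "id",
    "name",
    "slots",
    "calories_per_serving",
    "carbs_g",
    "protein_g",
    "fat_g",
    "serving_unit",
)


class AtwaterWarning(UserWarning):
    """Calories deviate from the Atwater reconstruction by more than 2%."""


@dataclass(frozen=True)
class MealRecord:
    """One meal with its per-serving nutrition."""

    id: str
    name: str
    slots: tuple[str, ...]
    calories_per_serving: float  # kcal
    carbs_g: float
    protein_g: float
    fat_g: float
    serving_unit: str = "1 serving"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("meal id must be non-empty")
        if not self.slots:
            raise ValidationError(f"meal {self.id!r}: slots must be non-empty")
        unknown = set(self.slots) - set(SLOTS)
        if unknown:
            raise ValidationError(f"meal {self.id!r}: unknown slots {sorted(unknown)}")
        if self.calories_per_serving <= 0:
            raise ValidationError(f"meal {self.id!r}: calories must be positive")
        for fname in ("carbs_g", "protein_g", "fat_g"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"meal {self.id!r}: {fname} must be >= 0")
        deviation = self.atwater_deviation()
        if deviation > ATWATER_HARD_TOLERANCE:
            raise ValidationError(
                f"meal {self.id!r}: calories {self.calories_per_serving} deviate "
                f"{deviation:.1%} from the Atwater value "
                f"{self.atwater_calories():.1f} (limit {ATWATER_HARD_TOLERANCE:.0%})"
            )
        if deviation > ATWATER_WARN_TOLERANCE:
            warnings.warn(
                f"meal {self.id!r}: calories deviate {deviation:.1%} from the "
                "Atwater reconstruction",
                AtwaterWarning,
                stacklevel=2,
            )

    def atwater_calories(self) -> float:
        """Calories implied by the macronutrient grams (4/4/9 factors)."""
        return (
            ATWATER_KCAL_PER_G["carbs"] * self.carbs_g
            + ATWATER_KCAL_PER_G["protein"] * self.protein_g
            + ATWATER_KCAL_PER_G["fat"] * self.fat_g
        )

    def atwater_deviation(self) -> float:
        """Relative gap between stated and Atwater-implied calories."""
        return abs(self.calories_per_serving - self.atwater_calories()) / (
            self.calories_per_serving
        )

    def calorie_shares(self) -> tuple[float, float, float]:
        """(carb, protein, fat) fractions of the stated calories."""
        c = self.calories_per_serving
        return (4.0 * self.carbs_g / c, 4.0 * self.protein_g / c, 9.0 * self.fat_g / c)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "slots": list(self.slots),
            "calories_per_serving": self.calories_per_serving,
            "carbs_g": self.carbs_g,
            "protein_g": self.protein_g,
            "fat_g": self.fat_g,
            "serving_unit": self.serving_unit,
        }


@dataclass(frozen=True)
class MealDatabase:
    """Ordered, validated collection of meals."""

    meals: tuple[MealRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.meals:
            raise ValidationError("meal database is empty")
        seen: set[str] = set()
        for meal in self.meals:
            if meal.id in seen:
                raise ValidationError(f"duplicate meal id {meal.id!r}")
            seen.add(meal.id)
        for slot in SLOTS:
            if not any(slot in m.slots for m in self.meals):
                raise ValidationError(f"no meal available for slot {slot!r}")

    def __len__(self) -> int:
        return len(self.meals)

    def __iter__(self):
        return iter(self.meals)

    def for_slot(self, slot: str) -> tuple[MealRecord, ...]:
        if slot not in SLOTS:
            raise DomainError(f"unknown slot {slot!r}")
        return tuple(m for m in self.meals if slot in m.slots)


def meal_from_dict(doc: dict) -> MealRecord:
    if not isinstance(doc, dict):
        raise ValidationError("meal entry must be a JSON object")
    missing = set(_MEAL_FIELDS) - doc.keys()
    if missing:
        raise ValidationError(f"meal entry missing fields: {sorted(missing)}")
    extra = doc.keys() - set(_MEAL_FIELDS)
    if extra:
        raise ValidationError(f"meal entry has unknown fields: {sorted(extra)}")
    slots = doc["slots"]
    if not isinstance(slots, (list, tuple)):
        raise ValidationError("meal slots must be a list")
    try:
        return MealRecord(
            id=str(doc["id"]),
            name=str(doc["name"]),
            slots=tuple(slots),
            calories_per_serving=float(doc["calories_per_serving"]),
            carbs_g=float(doc["carbs_g"]),
            protein_g=float(doc["protein_g"]),
            fat_g=float(doc["fat_g"]),
            serving_unit=str(doc["serving_unit"]),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError(f"malformed meal entry: {exc}") from exc


def load_meal_db(
    source: Union[str, IO[str], list], provenance: str = ""
) -> MealDatabase:
    """Load and validate a meal database.

    `source` may be a path, an open text stream, or an already-parsed JSON
    array.  Input order is preserved.
    """
    if isinstance(source, list):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    if not isinstance(doc, list):
        raise ValidationError("meal database document must be a JSON array")
    meals = tuple(meal_from_dict(entry) for entry in doc)
    return MealDatabase(meals=meals, provenance=provenance)


def write_meal_db(db: MealDatabase, target: Union[str, IO[str], None] = None):
    """Serialize a database back to its JSON document form.

    Key order is fixed so serialization is byte-stable; ``load(write(db))``
    is the identity on the meals.  With ``target=None`` the parsed document
    (a list of dicts) is returned instead of being written.
    """
    doc = [meal.to_dict() for meal in db.meals]
    if target is None:
        return doc
    text = json.dumps(doc, indent=2)
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return doc
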