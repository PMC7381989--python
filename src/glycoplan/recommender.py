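"""KNN-based meal recommendation and daily plan assembly.

The recommender treats each meal as a point in a 4-dimensional feature space:

* per-serving calories, z-scored over the database, and
* the carbohydrate, protein and fat calorie shares (raw fractions in [0, 1]).

A slot query (a calorie budget plus ideal macronutrient shares) is embedded in
the same space via the stored scaler, and the k nearest slot-eligible meals
under Euclidean distance are returned with inverse-distance weights, the
standard KNN-regression weighting.  An exact feature match (distance 0) is
pinned to rank 1 and flagged, since 1/d is undefined there.

Plan assembly splits the daily calorie target across breakfast/lunch/supper
(default 30/40/30), ranks candidates per slot, scales servings in quarter
steps, and searches the per-slot top-k lists (greedy order, effectively a
one-level backtrack over the candidate lists) for the first combination whose
totals pass the WHO validation rules: carbohydrate 40-65% of calories, protein
and fat 10-30% each, and total calories within 5% of the daily target.  If no
combination passes, the least-violating plan is returned flagged invalid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .energy import UserProfile, energy_requirement
from .errors import DomainError
from .mealdb import SLOTS, MealDatabase, MealRecord

#: Number of neighbours returned per slot.
DEFAULT_K = 5

#: Fraction of the daily calorie target allotted to each slot.
DEFAULT_SLOT_SPLIT = {"breakfast": 0.30, "lunch": 0.40, "supper": 0.30}

#: Ideal macronutrient calorie shares used to build slot queries: the
#: midpoints of the WHO ranges (carb 40-65%, protein 10-30%), fat making up
#: the remainder so the shares sum to one.
DEFAULT_IDEAL_SHARES = (0.525, 0.20, 0.275)

#: WHO macronutrient share windows, percent of total calories.
CARB_SHARE_RANGE = (40.0, 65.0)
PROTEIN_SHARE_RANGE = (10.0, 30.0)
FAT_SHARE_RANGE = (10.0, 30.0)

#: Allowed relative gap between plan calories and the daily target.
DEFAULT_CALORIE_TOLERANCE = 0.05

#: Serving amounts are quarter-multiples within this window.
SERVING_STEP = 0.25
SERVING_RANGE = (0.25, 3.0)


@dataclass(frozen=True)
class MealQuery:
    """A per-slot request: calorie budget plus ideal calorie shares."""

    slot: str
    slot_calorie_target: float
    ideal_shares: tuple[float, float, float] = DEFAULT_IDEAL_SHARES

    def __post_init__(self) -> None:
        if self.slot not in SLOTS:
            raise DomainError(f"unknown slot {self.slot!r}")
        if self.slot_calorie_target <= 0:
            raise DomainError("slot calorie target must be positive")
        if abs(sum(self.ideal_shares) - 1.0) > 1e-9:
            raise DomainError("ideal shares must sum to 1")


@dataclass(frozen=True)
class RankedMeal:
    """A meal with its query distance, weight, and scaled serving."""

    meal: MealRecord
    distance: float
    weight: float  # 1/distance; inf for an exact feature match
    exact_match: bool
    serving_amount: float  # quarter-multiples in [0.25, 3]
    scaled_calories: float
    scaled_carbs_g: float
    scaled_protein_g: float
    scaled_fat_g: float

    def to_dict(self) -> dict:
        return {
            "meal_id": self.meal.id,
            "name": self.meal.name,
            "distance": self.distance,
            "weight": self.weight,
            "serving_amount": self.serving_amount,
            "serving_unit": self.meal.serving_unit,
            "scaled_calories": self.scaled_calories,
            "scaled_carbs_g": self.scaled_carbs_g,
            "scaled_protein_g": self.scaled_protein_g,
            "scaled_fat_g": self.scaled_fat_g,
        }


@dataclass(frozen=True)
class ValidationReport:
    """Per-rule outcome of the WHO plan checks."""

    carb_share_ok: bool
    protein_share_ok: bool
    fat_share_ok: bool
    calories_ok: bool
    violations: tuple[str, ...]

    @property
    def valid(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class MealPlan:
    """Slot-wise chosen meals with totals, shares and validation outcome."""

    slots: dict[str, RankedMeal]
    daily_target: float
    total_calories: float
    total_carbs_g: float
    total_protein_g: float
    total_fat_g: float
    shares_pct: tuple[float, float, float]  # carb, protein, fat, % of kcal
    valid: bool
    violations: tuple[str, ...]
    candidates: dict[str, tuple[RankedMeal, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "daily_target": self.daily_target,
            "slots": {slot: rm.to_dict() for slot, rm in self.slots.items()},
            "total_calories": self.total_calories,
            "total_carbs_g": self.total_carbs_g,
            "total_protein_g": self.total_protein_g,
            "total_fat_g": self.total_fat_g,
            "shares_pct": {
                "carbs": self.shares_pct[0],
                "protein": self.shares_pct[1],
                "fat": self.shares_pct[2],
            },
            "valid": self.valid,
            "violations": list(self.violations),
        }


@dataclass(frozen=True)
class FeatureScaler:
    """Calorie z-score parameters, stored so queries transform identically."""

    calorie_mean: float
    calorie_std: float  # 0 for a degenerate (constant-calorie) database

    def transform_calories(self, calories: float) -> float:
        if self.calorie_std == 0.0:
            return 0.0
        return (calories - self.calorie_mean) / self.calorie_std


def featurize(db: MealDatabase) -> tuple[np.ndarray, FeatureScaler]:
    """Per-meal 4-vectors: z-scored calories and raw calorie shares.

    A single-meal (or constant-calorie) database has zero calorie variance;
    the z-score degenerates to 0 by convention.
    """
    calories = np.array([m.calories_per_serving for m in db.meals])
    mean = float(calories.mean())
    std = float(calories.std())
    scaler = FeatureScaler(calorie_mean=mean, calorie_std=std)
    z = np.zeros_like(calories) if std == 0.0 else (calories - mean) / std
    shares = np.array([m.calorie_shares() for m in db.meals])
    return np.column_stack([z, shares]), scaler


def query_vector(query: MealQuery, scaler: FeatureScaler) -> np.ndarray:
    """Embed a slot query into meal feature space."""
    return np.array(
        [scaler.transform_calories(query.slot_calorie_target), *query.ideal_shares]
    )


def scale_serving(meal: MealRecord, slot_target: float) -> tuple[float, float, float, float, float]:
    """Serving amount hitting the slot budget, plus scaled nutrition.

    The raw ratio ``slot_target / calories_per_serving`` is rounded to the
    nearest quarter (halves round up) and clamped to [0.25, 3].
    Returns ``(serving, calories, carbs_g, protein_g, fat_g)``.
    """
    if slot_target <= 0:
        raise DomainError("slot target must be positive")
    raw = slot_target / meal.calories_per_serving
    serving = math.floor(raw / SERVING_STEP + 0.5) * SERVING_STEP
    serving = min(max(serving, SERVING_RANGE[0]), SERVING_RANGE[1])
    return (
        serving,
        serving * meal.calories_per_serving,
        serving * meal.carbs_g,
        serving * meal.protein_g,
        serving * meal.fat_g,
    )


def knn_rank(
    query: MealQuery,
    db: MealDatabase,
    k: int = DEFAULT_K,
    *,
    features: Optional[np.ndarray] = None,
    scaler: Optional[FeatureScaler] = None,
) -> list[RankedMeal]:
    """The k nearest slot-eligible meals under Euclidean feature distance.

    Sorted by ascending distance, ties broken by meal id.  Weights are
    1/distance; a zero-distance meal is pinned first with infinite weight and
    ``exact_match=True``.  Precomputed ``features``/``scaler`` (from
    :func:`featurize`) may be passed to avoid re-scanning the database.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    if features is None or scaler is None:
        features, scaler = featurize(db)
    eligible = [i for i, m in enumerate(db.meals) if query.slot in m.slots]
    if not eligible:
        raise DomainError(f"no meal eligible for slot {query.slot!r}")
    qvec = query_vector(query, scaler)
    dists = np.linalg.norm(features[eligible] - qvec, axis=1)
    order = sorted(range(len(eligible)), key=lambda j: (dists[j], db.meals[eligible[j]].id))
    ranked = []
    for j in order[:k]:
        meal = db.meals[eligible[j]]
        d = float(dists[j])
        serving, cal, carbs, protein, fat = scale_serving(meal, query.slot_calorie_target)
        ranked.append(
            RankedMeal(
                meal=meal,
                distance=d,
                weight=math.inf if d == 0.0 else 1.0 / d,
                exact_match=d == 0.0,
                serving_amount=serving,
                scaled_calories=cal,
                scaled_carbs_g=carbs,
                scaled_protein_g=protein,
                scaled_fat_g=fat,
            )
        )
    return ranked


def _plan_from_choice(
    choice: dict[str, RankedMeal],
    daily_target: float,
    report: ValidationReport,
    candidates: dict[str, tuple[RankedMeal, ...]],
) -> MealPlan:
    total_cal = sum(rm.scaled_calories for rm in choice.values())
    carbs = sum(rm.scaled_carbs_g for rm in choice.values())
    protein = sum(rm.scaled_protein_g for rm in choice.values())
    fat = sum(rm.scaled_fat_g for rm in choice.values())
    return MealPlan(
        slots=dict(choice),
        daily_target=daily_target,
        total_calories=total_cal,
        total_carbs_g=carbs,
        total_protein_g=protein,
        total_fat_g=fat,
        shares_pct=_shares_pct(total_cal, carbs, protein, fat),
        valid=report.valid,
        violations=report.violations,
        candidates=candidates,
    )


def _shares_pct(total_cal, carbs_g, protein_g, fat_g) -> tuple[float, float, float]:
    if total_cal <= 0:
        raise DomainError("plan has no calories")
    return (
        100.0 * 4.0 * carbs_g / total_cal,
        100.0 * 4.0 * protein_g / total_cal,
        100.0 * 9.0 * fat_g / total_cal,
    )


def check_totals(
    total_calories: float,
    carbs_g: float,
    protein_g: float,
    fat_g: float,
    daily_target: float,
    *,
    calorie_tolerance: float = DEFAULT_CALORIE_TOLERANCE,
) -> ValidationReport:
    """Apply the WHO share windows and the calorie-closeness rule."""
    carb_pct, protein_pct, fat_pct = _shares_pct(total_calories, carbs_g, protein_g, fat_g)
    violations = []
    carb_ok = CARB_SHARE_RANGE[0] <= carb_pct <= CARB_SHARE_RANGE[1]
    if not carb_ok:
        violations.append(
            f"carb share {carb_pct:.1f}% outside {CARB_SHARE_RANGE[0]:.0f}-{CARB_SHARE_RANGE[1]:.0f}%"
        )
    protein_ok = PROTEIN_SHARE_RANGE[0] <= protein_pct <= PROTEIN_SHARE_RANGE[1]
    if not protein_ok:
        violations.append(
            f"protein share {protein_pct:.1f}% outside {PROTEIN_SHARE_RANGE[0]:.0f}-{PROTEIN_SHARE_RANGE[1]:.0f}%"
        )
    fat_ok = FAT_SHARE_RANGE[0] <= fat_pct <= FAT_SHARE_RANGE[1]
    if not fat_ok:
        violations.append(
            f"fat share {fat_pct:.1f}% outside {FAT_SHARE_RANGE[0]:.0f}-{FAT_SHARE_RANGE[1]:.0f}%"
        )
    calorie_gap = abs(total_calories - daily_target) / daily_target
    calories_ok = calorie_gap <= calorie_tolerance
    if not calories_ok:
        violations.append(
            f"total {total_calories:.0f} kcal off target {daily_target:.0f} by "
            f"{100 * calorie_gap:.1f}% (limit {100 * calorie_tolerance:.0f}%)"
        )
    return ValidationReport(
        carb_share_ok=carb_ok,
        protein_share_ok=protein_ok,
        fat_share_ok=fat_ok,
        calories_ok=calories_ok,
        violations=tuple(violations),
    )


def validate_plan(
    plan: MealPlan, *, calorie_tolerance: float = DEFAULT_CALORIE_TOLERANCE
) -> ValidationReport:
    """Re-check an assembled plan against the WHO rules."""
    return check_totals(
        plan.total_calories,
        plan.total_carbs_g,
        plan.total_protein_g,
        plan.total_fat_g,
        plan.daily_target,
        calorie_tolerance=calorie_tolerance,
    )


def assemble_plan(
    profile: UserProfile,
    db: MealDatabase,
    *,
    k: int = DEFAULT_K,
    slot_split: Optional[dict[str, float]] = None,
    ideal_shares: tuple[float, float, float] = DEFAULT_IDEAL_SHARES,
    calorie_tolerance: float = DEFAULT_CALORIE_TOLERANCE,
    daily_target: Optional[float] = None,
) -> MealPlan:
    """Assemble and validate a breakfast/lunch/supper plan for a profile.

    The daily calorie target comes from the energy pipeline unless given
    explicitly.  Per slot, the top-k ranked meals are candidates; candidate
    triples are tried in ascending total-rank order (rank-1 everywhere first,
    then single-slot backtracks, and so on) and the first triple passing
    validation wins.  If none passes, the triple with the fewest violations
    (then smallest calorie gap) is returned with ``valid=False``.
    """
    split = dict(DEFAULT_SLOT_SPLIT if slot_split is None else slot_split)
    if set(split) != set(SLOTS):
        raise DomainError(f"slot split must cover exactly {SLOTS}")
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise DomainError("slot split fractions must sum to 1")
    if daily_target is None:
        daily_target = energy_requirement(profile).daily_target
    features, scaler = featurize(db)
    candidates: dict[str, tuple[RankedMeal, ...]] = {}
    for slot in SLOTS:
        query = MealQuery(
            slot=slot,
            slot_calorie_target=split[slot] * daily_target,
            ideal_shares=ideal_shares,
        )
        candidates[slot] = tuple(
            knn_rank(query, db, k, features=features, scaler=scaler)
        )

    best_choice = None
    best_report = None
    best_key = None
    index_lists = [range(len(candidates[slot])) for slot in SLOTS]
    combos = sorted(itertools.product(*index_lists), key=lambda idx: (sum(idx), idx))
    for idx in combos:
        choice = {slot: candidates[slot][i] for slot, i in zip(SLOTS, idx)}
        total_cal = sum(rm.scaled_calories for rm in choice.values())
        report = check_totals(
            total_cal,
            sum(rm.scaled_carbs_g for rm in choice.values()),
            sum(rm.scaled_protein_g for rm in choice.values()),
            sum(rm.scaled_fat_g for rm in choice.values()),
            daily_target,
            calorie_tolerance=calorie_tolerance,
        )
        if report.valid:
            return _plan_from_choice(choice, daily_target, report, candidates)
        key = (len(report.violations), abs(total_cal - daily_target))
        if best_key is None or key < best_key:
            best_choice, best_report, best_key = choice, report, key
    return _plan_from_choice(best_choice, daily_target, best_report, candidates)
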