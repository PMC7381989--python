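"""Seeded synthetic data standing in for every external asset.

The original system drew on private assets: a nutrition database, a
25-class x 300-image food photo corpus (consumed here as bottleneck feature
vectors), FAQ text scraped from diabetes communities, and live glucose/GPS
logs.  None of those are redistributable, so each is emulated by a
deterministic generator: same seed, bit-identical output.  Generated
artifacts always satisfy the consuming module's validators (an explicit test
property), so any module can be exercised end to end with no downloads.

What the generators do and do not emulate is documented in the methods note;
briefly, they reproduce the statistical structure the algorithms rely on
(Atwater-consistent nutrition, linearly separable feature clusters, shared
vocabulary between a question and its re-query, circadian glucose pattern)
but make no claim of nutritional or clinical realism.
"""

from __future__ import annotations

import math
from datetime import date, datetime, time, timedelta

import numpy as np

from .classifier import BottleneckDataset
from .energy import ACTIVITY_LEVELS, GOALS, UserProfile
from .errors import DomainError
from .mealdb import SLOTS, MealDatabase, MealRecord
from .qna import QAPair
from .tracking import EARTH_RADIUS_KM, GeoTrace, GlucoseReading

# Meal-name parts for synthetic records (flavour only; nutrition is drawn
# independently of the name).
_MEAL_BASES = (
    "jollof rice", "fried rice", "plain rice", "banku", "fufu", "kenkey",
    "waakye", "yam porridge", "plantain", "tuo zaafi", "oat porridge",
    "beans stew", "kontomire stew", "palava sauce", "light soup",
    "groundnut soup", "okro soup", "palm nut soup", "garden egg stew",
    "chicken salad", "grilled tilapia", "boiled eggs", "vegetable noodles",
    "millet porridge", "couscous",
)
_SERVING_UNITS = ("1 ladle", "1 bowl", "1 plate", "1 cup", "2 pieces")

#: Shares drawn per meal: carbohydrate and protein calorie fractions, fat
#: taking the remainder (resampled while the remainder is negative).
CARB_SHARE_RANGE = (0.35, 0.70)
PROTEIN_SHARE_RANGE = (0.08, 0.35)
CALORIES_RANGE = (150.0, 800.0)

#: Calories of the three slot-coverage anchor meals.  With quarter servings
#: in [0.25, 3], any calories-per-serving in [470, 800] can hit every slot
#: budget arising from daily targets in [1000, 3500] (slot shares 30-40%).
ANCHOR_CALORIES_RANGE = (470.0, 800.0)

#: Class names for the default 25-class feature generator.
FOOD_CLASS_NAMES = (
    "jollof_rice", "fried_rice", "waakye", "banku_tilapia", "fufu_palm_nut",
    "fufu_light_soup", "kenkey_fish", "plantain_palava_sauce",
    "plantain_beans", "tuo_zaafi", "omo_tuo", "yam_porridge", "gari_foto",
    "kontomire_stew", "okro_soup", "groundnut_soup", "chicken_salad",
    "grilled_tilapia", "boiled_yam_egg", "pizza", "cheeseburger", "fries",
    "fried_chicken", "spring_rolls", "doughnut",
)


def gen_meal_db(n: int, seed: int = 0) -> MealDatabase:
    """A synthetic meal database of `n` Atwater-exact records.

    Macronutrient calorie shares are drawn around dietetic ranges
    (carbohydrate U[0.35, 0.70], protein U[0.08, 0.35], fat the remainder,
    redrawn while negative); calories per serving are U[150, 800] and grams
    are back-computed through the Atwater factors, so records always load
    cleanly.  Slots rotate so each slot holds at least n/3 meals, and the
    first three meals anchor each slot with calories chosen so every slot
    budget from daily targets in [1000, 3500] is reachable.
    """
    if n < 3:
        raise DomainError("need at least 3 meals (one per slot)")
    rng = np.random.default_rng(seed)
    meals = []
    for i in range(n):
        while True:
            carb = rng.uniform(*CARB_SHARE_RANGE)
            protein = rng.uniform(*PROTEIN_SHARE_RANGE)
            fat = 1.0 - carb - protein
            if fat >= 0.0:
                break
        if i < len(SLOTS):
            calories = rng.uniform(*ANCHOR_CALORIES_RANGE)
        else:
            calories = rng.uniform(*CALORIES_RANGE)
        slots = [SLOTS[i % len(SLOTS)]]
        if rng.random() < 0.3:
            extra = SLOTS[int(rng.integers(len(SLOTS)))]
            if extra not in slots:
                slots.append(extra)
        base = _MEAL_BASES[int(rng.integers(len(_MEAL_BASES)))]
        meals.append(
            MealRecord(
                id=f"m{i:04d}",
                name=f"{base} #{i}",
                slots=tuple(slots),
                calories_per_serving=calories,
                carbs_g=carb * calories / 4.0,
                protein_g=protein * calories / 4.0,
                fat_g=fat * calories / 9.0,
                serving_unit=_SERVING_UNITS[int(rng.integers(len(_SERVING_UNITS)))],
            )
        )
    return MealDatabase(meals=tuple(meals), provenance=f"synthetic seed={seed}")


def gen_profile(seed: int = 0) -> UserProfile:
    """One synthetic adult profile drawn from realistic ranges."""
    rng = np.random.default_rng(seed)
    sex = "male" if rng.random() < 0.5 else "female"
    return UserProfile(
        id=f"user-{seed}",
        sex=sex,
        age=float(rng.uniform(20, 75)),
        weight=float(rng.uniform(50, 110)),
        height=float(rng.uniform(150, 195)),
        activity_level=ACTIVITY_LEVELS[int(rng.integers(len(ACTIVITY_LEVELS)))],
        goal=GOALS[int(rng.integers(len(GOALS)))],
    )


def gen_bottleneck_features(
    n_classes: int = 25,
    n_per_class: int = 300,
    n_features: int = 64,
    separation: float = 6.0,
    noise: float = 1.0,
    seed: int = 0,
) -> BottleneckDataset:
    """Per-class Gaussian clusters shaped like a bottleneck-feature corpus.

    Class centres are random directions rescaled so the minimum pairwise
    distance equals ``separation * noise``; samples are centre plus isotropic
    Gaussian noise.  ``separation=0`` collapses all centres to the origin
    (class-indistinguishable data); the default 6-sigma separation makes the
    classes linearly separable for all practical purposes.
    """
    if n_classes < 2 or n_per_class < 2:
        raise DomainError("need at least 2 classes with 2 samples each")
    if n_features < 1:
        raise DomainError("need at least 1 feature dimension")
    if separation < 0 or noise < 0:
        raise DomainError("separation and noise must be non-negative")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_classes, n_features))
    if separation == 0.0:
        centers[:] = 0.0
    else:
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.linalg.norm(diffs, axis=-1)
        min_dist = dists[np.triu_indices(n_classes, k=1)].min()
        centers *= separation * noise / min_dist
    features = np.empty((n_classes * n_per_class, n_features))
    labels = np.empty(n_classes * n_per_class, dtype=int)
    for c in range(n_classes):
        block = slice(c * n_per_class, (c + 1) * n_per_class)
        features[block] = centers[c] + noise * rng.standard_normal(
            (n_per_class, n_features)
        )
        labels[block] = c
    if n_classes <= len(FOOD_CLASS_NAMES):
        names = FOOD_CLASS_NAMES[:n_classes]
    else:
        names = tuple(f"class_{c}" for c in range(n_classes))
    return BottleneckDataset(features=features, labels=labels, class_names=names)


_QA_FOODS = (
    "plantain", "rice", "fufu", "kenkey", "waakye", "banku", "pizza",
    "cheeseburger", "fries", "honey", "mango", "watermelon", "yam",
    "beans", "oats", "bread", "pasta", "cassava", "millet", "doughnuts",
)
_QA_TOPICS = (
    "insulin", "metformin", "exercise", "hypoglycaemia", "hyperglycaemia",
    "neuropathy", "retinopathy", "ketones", "carbohydrates", "fibre",
)
# Each template family uses a disjoint sentence frame, and fillers within a
# family are distinct, so generated questions never share a full token set.
_QA_TEMPLATES = (
    (
        "Can a diabetic eat {x}?",
        "{x} can fit a diabetic diet in small portions; check how it affects "
        "your blood sugar and prefer low glycaemic preparations.",
        _QA_FOODS,
    ),
    (
        "How does {x} raise blood sugar?",
        "{x} raises blood sugar mainly through its carbohydrate content; "
        "pair it with protein or fibre to slow the rise.",
        _QA_FOODS,
    ),
    (
        "How much {x} is safe per meal?",
        "Portion {x} so carbohydrates stay near your per-meal budget; a "
        "dietitian can personalise the amount.",
        _QA_FOODS,
    ),
    (
        "Why does my doctor talk about {x}?",
        "{x} matters in diabetes care because it directly affects how your "
        "blood glucose is controlled over time.",
        _QA_TOPICS,
    ),
    (
        "Tell me about {x} and diabetes management.",
        "Managing diabetes involves understanding {x}; ask your care team "
        "how it applies to your treatment plan.",
        _QA_TOPICS,
    ),
)


def gen_qa_pairs(n: int, seed: int = 0) -> list[QAPair]:
    """`n` templated diabetes FAQ pairs with pairwise-distinct questions.

    Questions are slot-filled from food/topic vocabularies; when the template
    pool is exhausted, numbered glucose-reading questions extend it without
    bound.  Selection order is a seeded permutation of the pool.
    """
    if n < 1:
        raise DomainError("need at least one pair")
    pool = [
        (tpl.format(x=word), ans.format(x=word))
        for tpl, ans, vocab in _QA_TEMPLATES
        for word in vocab
    ]
    reading = 60
    while len(pool) < n:
        pool.append(
            (
                f"Is a glucose reading of {reading} serious?",
                f"A reading of {reading} mg/dL should be discussed with your "
                "doctor; persistent values outside 70-180 mg/dL need review.",
            )
        )
        reading += 5
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))[:n]
    return [
        QAPair(question=pool[i][0], answer=pool[i][1], source=f"synthetic seed={seed}")
        for i in order
    ]


def gen_glucose_series(
    days: int, seed: int = 0, start: date = date(2024, 1, 1)
) -> list[GlucoseReading]:
    """A circadian glucose log: 3-5 readings/day with post-meal spikes.

    Each day draws a baseline U[90, 130] mg/dL; fasting/pre-meal/bedtime
    readings sit near baseline and post-meal readings add a U[40, 100] spike,
    all with Gaussian jitter (sigma 5 mg/dL) and clipped to the sanity
    window.  Tags follow the time of day.
    """
    if days < 1:
        raise DomainError("days must be >= 1")
    rng = np.random.default_rng(seed)
    # (hour, minute, tag, spiked) candidates in daily order; the first three
    # always fire, the last two with probability 1/2 each.
    slots = (
        (7, 0, "fasting", False),
        (13, 30, "post_meal", True),
        (22, 0, "bedtime", False),
        (9, 30, "post_meal", True),
        (18, 0, "pre_meal", False),
    )
    readings = []
    for d in range(days):
        day = start + timedelta(days=d)
        baseline = rng.uniform(90, 130)
        take = [True, True, True, rng.random() < 0.5, rng.random() < 0.5]
        for (hour, minute, tag, spiked), chosen in zip(slots, take):
            if not chosen:
                continue
            value = baseline + (rng.uniform(40, 100) if spiked else 0.0)
            value += rng.normal(0.0, 5.0)
            value = float(np.clip(value, 20.0, 500.0))
            readings.append(
                GlucoseReading(
                    timestamp=datetime.combine(day, time(hour, minute)),
                    value=value,
                    tag=tag,
                )
            )
    readings.sort(key=lambda r: r.timestamp)
    return readings


def gen_geo_trace(
    n_points: int,
    step_m: float = 50.0,
    seed: int = 0,
    start_lat: float = 5.6500,
    start_lon: float = -0.1870,
    bearing_deg: float = None,
    walk_speed_kmh: float = 5.0,
    start_time: datetime = datetime(2024, 1, 1, 6, 0),
) -> GeoTrace:
    """A random-walk GPS trace with ~`step_m`-metre great-circle steps.

    Headings drift smoothly (wrapped Gaussian increments) unless a constant
    `bearing_deg` is given; timestamps advance at `walk_speed_kmh`.
    """
    if n_points < 2:
        raise DomainError("need at least 2 points")
    if step_m <= 0:
        raise DomainError("step must be positive")
    rng = np.random.default_rng(seed)
    step_rad = (step_m / 1000.0) / EARTH_RADIUS_KM
    dt = timedelta(hours=(step_m / 1000.0) / walk_speed_kmh)
    lat, lon = math.radians(start_lat), math.radians(start_lon)
    heading = (
        math.radians(bearing_deg)
        if bearing_deg is not None
        else rng.uniform(0.0, 2.0 * math.pi)
    )
    points = [(start_time, start_lat, start_lon)]
    ts = start_time
    for _ in range(n_points - 1):
        if bearing_deg is None:
            heading += rng.normal(0.0, 0.3)
        # Direct geodesic problem on the sphere for one step.
        new_lat = math.asin(
            math.sin(lat) * math.cos(step_rad)
            + math.cos(lat) * math.sin(step_rad) * math.cos(heading)
        )
        new_lon = lon + math.atan2(
            math.sin(heading) * math.sin(step_rad) * math.cos(lat),
            math.cos(step_rad) - math.sin(lat) * math.sin(new_lat),
        )
        lat, lon = new_lat, new_lon
        ts = ts + dt
        points.append((ts, math.degrees(lat), math.degrees(lon)))
    return GeoTrace(points=tuple(points))
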