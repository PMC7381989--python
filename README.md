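# glycoplan

Nutrition-aware decision support for diabetes self-management: a Python
library and `glycoplan` CLI covering the computational core of a
diabetes-management app — daily calorie targets, KNN meal recommendation,
transfer-learning food classification, FAQ retrieval, and glucose/activity
tracking — with seeded synthetic data standing in for the private assets
(nutrition databases, food-image corpora, scraped FAQ text) such systems
normally rely on.

## What it computes

**Energy requirements.** Basal metabolic rate from the revised
Harris-Benedict equation,

```
BMR_male   = 88.362 + 13.397 w + 4.799 h − 5.677 a
BMR_female = 447.593 + 9.247 w + 3.098 h − 4.330 a
```

(w kg, h cm, a years), scaled by a lifestyle multiplier (1.2–1.9) and
shifted ±500 kcal/day for a lose/gain goal, floored at 1200 kcal/day.
BMI classifies the diet type by WHO cutpoints (18.5 / 25 / 30 kg/m²).

**Meal recommendation.** Each meal is a point in a 4-feature space:
z-scored calories per serving plus the carbohydrate/protein/fat calorie
shares (Atwater factors 4/4/9 kcal/g). A slot query (calorie budget +
ideal shares) is ranked against eligible meals by Euclidean distance with
inverse-distance weights w_i = 1/d_i (k = 5 neighbours). Servings scale in
quarter steps within [0.25, 3]; the daily plan splits the target 30/40/30
across breakfast/lunch/supper and must satisfy the WHO windows —
carbohydrate 40–65 %, protein 10–30 %, fat 10–30 % of calories — and land
within 5 % of the daily target, or it is returned flagged invalid with the
violations listed.

**Food classification.** A softmax head over precomputed bottleneck
features (the penultimate-layer activations of a frozen image network):
stratified 80/10/10 split, minibatches of 10 drawn with replacement, SGD on
the analytic softmax cross-entropy gradient, loss/accuracy traces, and an
argmax prediction with confidence and a recommended/not-recommended flag.

**FAQ retrieval.** TF-IDF (tf = raw count, idf = ln((1+N)/(1+df)) + 1,
L2-normalised) over stored questions, cosine-ranked against the query; the
best answer is returned iff its score reaches the threshold (default 0.3),
otherwise "no answer".

**Tracking.** Haversine great-circle distance over GPS traces (R =
6371.0088 km), duration from speed, medication-reminder expansion, glucose
summaries with time-in-range (70–180 mg/dL), and structured reports.

## Worked example

```
$ glycoplan synth meals --n 200 --seed 0 --out meals.json
$ glycoplan synth profile --seed 7 --out p7.json
$ glycoplan energy --profile p7.json
{
  "bmr": 1536.1336023175222,
  "activity_multiplier": 1.2,
  "goal_adjustment": -500.0,
  "daily_target": 1343.3603227810265,
  "bmi": 37.648143926713935,
  "diet_type": "obese"
}
```

A sedentary 69-year-old woman (96.5 kg, 160 cm) aiming to lose weight has a
resting expenditure of 1536 kcal/day; with the sedentary multiplier and the
−500 kcal goal adjustment her daily target is 1343 kcal. Her BMI (37.6)
falls in the obese class, consistent with the lose goal.

```
$ glycoplan recommend --profile p7.json --meals meals.json
{
  "daily_target": 1343.3603227810265,
  ...
  "total_calories": 1402.0290145396175,
  "shares_pct": {
    "carbs": 52.38889368883157,
    "protein": 20.167679600386062,
    "fat": 27.44342671078235
  },
  "valid": true,
  "violations": []
}
```

The assembled plan (one ranked meal per slot, one serving each) totals
1402 kcal — within 5 % of the 1343 kcal target — with 52 % of calories from
carbohydrate, 20 % from protein and 27 % from fat, inside all three WHO
windows, so the plan validates.

Other entry points follow the same pattern: `glycoplan classify
train|eval|predict`, `glycoplan qna --kb faq.tsv --ask "..."`, `glycoplan
glucose summary|report`, `glycoplan activity --trace walk.csv`, `glycoplan
remind --spec rx.json`, and `glycoplan synth ...` to produce any input.

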