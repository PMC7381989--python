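# Methods

This note records the models glycoplan implements, the defaults it pins,
the choices that were genuinely open, and what the synthetic data does and
does not establish.

## Energy model

Daily energy needs are the revised Harris-Benedict basal metabolic rate
(Roza–Shizgal 1984 coefficients, pinned in
`energy.HARRIS_BENEDICT_COEFFS`) multiplied by a lifestyle factor and
shifted for the weight goal:

| parameter | default | why |
|---|---|---|
| activity multipliers | 1.2 / 1.375 / 1.55 / 1.725 / 1.9 | standard dietetic TDEE table |
| goal adjustment | ±500 kcal/day | conventional ~0.5 kg/week pace |
| safety floor | 1200 kcal/day | prevents pathological lose-weight targets |
| BMI cutpoints | 18.5 / 25 / 30 kg/m², lower bound inclusive | WHO classes |

The revised form was chosen over the 1919 original as the most widely used
modern re-fit; Mifflin-St Jeor would slot in behind the same interface but
is deliberately out of scope. One caveat worth knowing: the male-female BMR
gap under these coefficients is `-359.231 + 4.15 w + 1.701 h - 1.347 a`,
which is positive across the ordinary adult range but flips sign for very
small, very old profiles — the equations are population fits, not
physiological laws.

"Diet type" is interpreted as the BMI class (each class also implies a
default goal — underweight→gain, normal→maintain, otherwise→lose — which an
explicit user goal overrides). Nothing downstream depends on any other
reading of the term.

## Meal knowledge base

Meals carry per-serving calories, macronutrient grams, slot tags and a
serving unit. Calories must agree with the Atwater reconstruction
(4·carbs + 4·protein + 9·fat) within 10 % — a hard error beyond that, a
warning beyond 2 %. The 10 % band absorbs the rounding, fibre and
water-content effects real food tables show while still catching corrupt
records. Slot tags (breakfast/lunch/supper) are part of the schema because
plan assembly needs them; they are the package's addition to an otherwise
conventional nutrition record.

## Recommender

The KNN feature space is the module's central design decision, since
nothing about it is forced by the problem statement:

* features: per-serving calories z-scored over the database, plus the three
  calorie shares raw in [0, 1]. The z-score makes the calorie axis
  commensurate with the share axes; with a typical database (calorie SD a
  few hundred kcal) one share-unit of distance corresponds to a few hundred
  kcal, so both axes matter in ranking.
* query: the slot calorie budget transformed by the stored scaler plus
  ideal shares — the midpoints of the WHO windows, (0.525, 0.20, 0.275).
  The query is built from the user's requirement, not from a liked meal;
  with no preference history the requirement vector is the only grounded
  choice.
* metric: Euclidean; weights 1/d with an exact match (d = 0) pinned to rank
  1 and flagged, the standard KNN-regression convention for the 1/d
  singularity. Ties break by meal id for determinism.
* a degenerate database (single meal, or constant calories) has zero
  calorie variance; the z-score is defined as 0 there.

Serving amounts are quarter-multiples in [0.25, 3] — kitchen-realistic
granularity; the ratio rounds half-up. Plan assembly takes the top k = 5
candidates per slot (slot split 30/40/30, configurable) and tries candidate
triples in ascending total-rank order — rank-1 everywhere first, then
single-slot backtracks, and so on — accepting the first triple that passes
validation; otherwise the least-violating triple is returned with
`valid = false`. This greedy-with-backtracking scheme is the simplest
deterministic way to turn per-slot rankings into a day plan; at k = 5 it
examines at most 125 triples, so exhaustiveness over the candidate lists is
cheap.

Validation: carbohydrate 40–65 %, protein 10–30 %, fat 10–30 % of plan
calories, and total within 5 % of the daily target. The 5 % calorie band is
a deliberately safe default (a well-stocked database typically achieves
well under 1 % slack); it is a parameter, not a constant.

## Classification head

Only the output layer of a transfer-learning food classifier is trained
here; the convolutional feature extractor is consumed as fixed bottleneck
vectors. The training problem — softmax regression — is convex, which
drives several defaults:

| parameter | default | why |
|---|---|---|
| init | W = 0, b = 0 | convex problem; deterministic, no init variance |
| steps | 4000 | past the accuracy plateau on the benchmark |
| batch | 10, sampled with replacement | small-batch SGD; replacement keeps steps i.i.d. |
| learning rate | 0.01 | stable for z-scale features; configurable |
| split | 80/10/10 stratified per class | floor(r·n_c) to train/validation, remainder to test |
| eval interval | 100 steps | trace granularity |

Cross-entropy is reported in nats and the probability is clipped at 1e-12
before the log. The gradient is the analytic softmax-CE form
(∂L/∂logits = p − onehot, batch-averaged); tests check it against central
finite differences rather than trusting the algebra. Image distortions /
augmentation are intentionally absent: they act on pixels, which this
package never sees.

## FAQ retrieval

The scoring scheme is pinned exactly — tf = raw count,
idf = ln((1+N)/(1+df)) + 1, rows L2-normalised, cosine ranking, ties by
stored order, answer iff top score ≥ 0.3 — so that behaviour is testable to
machine precision (the formula coincides with scikit-learn's smoothed
TF-IDF, which the tests use as an independent oracle). Tokenization is
lowercase, punctuation-stripped, whitespace-split, minus a small shipped
stopword list; stemming is off by default because the templated corpora and
short user queries share surface forms. The 0.3 threshold separates
"shares meaningful vocabulary" from "incidental overlap" for short
questions; it is a parameter of `answer`.

## Tracking

Distances use the haversine formula with the IUGG mean Earth radius
6371.0088 km — metre-accurate at walking scales, with no need for an
ellipsoid. Glucose is stored in mg/dL (a mmol/L conversion utility uses the
18.016 factor); readings outside (10, 1000) mg/dL are rejected as sensor
or entry errors. Time-in-range uses the consensus 70–180 mg/dL window,
inclusive. Timestamps are timezone-naive local times: the intended context
is a single user's own log. Reports are emitted as JSON and plain text; a
PDF renderer is a pluggable consumer of the JSON form, not a core
dependency.

## Synthetic data: what it emulates, what it does not

Every generator is a pure function of its arguments including the seed
(bit-reproducibility is a test property), and every generated artifact
passes the consuming module's validators.

* `gen_meal_db(n, seed)` — calorie shares carb ~ U[0.35, 0.70], protein ~
  U[0.08, 0.35], fat the remainder (redrawn while negative); calories/serving
  U[150, 800]; grams back-computed so Atwater consistency is exact. Slots
  rotate so every slot holds ≥ n/3 meals, and three anchor meals with
  calories in [470, 800] guarantee every slot budget arising from daily
  targets in [1000, 3500] is reachable at quarter-serving granularity.
* `gen_profile(seed)` — adult profiles: age U[20, 75], weight U[50, 110] kg,
  height U[150, 195] cm, uniform sex/activity/goal. Extreme corners of this
  space can push the daily target above the meal generator's 3500 kcal
  coverage bound; such plans legitimately come back `valid = false`.
* `gen_bottleneck_features(C, n, d, separation, noise, seed)` — Gaussian
  class clusters with centres rescaled to minimum pairwise distance
  separation·noise. The default 25 classes × 300 samples × 64 dims at
  6-sigma separation is linearly separable by construction; separation 0
  collapses all classes. This emulates the geometry of bottleneck features
  of visually distinct dishes, not any particular network's embedding.
* `gen_qa_pairs(n, seed)` — template-filled diabetes FAQ text whose
  questions have pairwise-distinct token sets, so verbatim self-retrieval at
  cosine 1 is unambiguous.
* `gen_glucose_series(days, seed)` — 3–5 readings/day, baseline U[90, 130]
  mg/dL, post-meal spikes +U[40, 100], Gaussian jitter (σ = 5), tags
  following the time of day.
* `gen_geo_trace(n, step_m, seed)` — spherical random walk with smoothly
  drifting heading and exact per-step great-circle length; an optional fixed
  bearing supports closed-form checks along the equator.

Because the generators produce exactly the structure the algorithms
exploit — separable clusters, Atwater-exact nutrition, vocabulary-sharing
questions — passing tests demonstrate algorithmic correctness and
end-to-end wiring, **not** performance on real food images, real nutrition
tables, or real patient logs. In particular the ≥ 95 % classifier accuracy
on the synthetic benchmark says nothing about accuracy on photographs; it
says the training loop solves a problem of the stated shape.

## Problem sizes

The test suite and the acceptance script run the full stated conditions —
the 25 × 300 × 64 classifier benchmark with 4000 training steps, 200
knn-vs-brute-force databases, and the 100-profile × 500-meal plan
simulation — since the whole suite completes in a few seconds on one CPU;
no scaling down was needed.

## Known limitations

* The recommender has no preference learning or meal-history model; two
  users with the same profile get the same plan.
* Plan assembly optimises feasibility, not variety; it may pick the same
  well-matched meal for a slot day after day.
* The Q&A engine is lexical; paraphrases sharing no vocabulary with a
  stored question fall to "no answer" even when on topic.
* The classifier head assumes the upstream feature extractor is fixed and
  informative; nothing here can recover from poor features.
* Glucose timestamps are naive; cross-timezone logs would need explicit
  handling upstream.
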