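# Methods

## Scope and design

The package implements the canonical mobility-based depression prediction
pipeline — DBSCAN significant locations, a 170-feature GPS representation
plus 6 step features, ICD-10 symptom scoring of repeated surveys, and
nested Monte-Carlo cross-validated classification — together with a
synthetic cohort generator whose purpose is to realize, under controlled
conditions, the contrast between homogeneous and heterogeneous cohorts.
Everything downstream of the generator treats its output exactly like real
exports (four CSV tables), so the pipeline code never knows whether data is
simulated.

## Generative model

### Lifestyle and movement

Each participant owns a set of anchors (home, work, and ~4 "other" places
0.5–4 km from home; homes fall in a disk of radius `geo_spread_km` around
the cohort center) and a 24-hour occupancy schedule: home probability 0.97
at night (22:00–06:00), a daytime home weight around 0.35, a work share
that peaks 09:00–18:00, the remainder split over other anchors. Movement is
semi-Markov anchor-hopping: per day, `Poisson(transition_rate)` transitions
at uniform times in 07:00–22:00, each jumping to an anchor drawn from the
current hour's schedule (excluding the current one), with straight-line
interpolated waypoints during a 10-minute transit. This is deliberately the
simplest generator that yields DBSCAN-recoverable significant locations and
realistic dwell/transition structure; the features only need that
structure, not road networks.

Reference (base) lifestyle values: 8 transitions/day, 6 anchors,
7000 steps/day, daytime home weight 0.35. These define the *reference
population SD* unit via a fixed relative SD of 0.25.

### Depression effect and heterogeneity

- **Effect size** (`effect_size`, default 1.0): a depressed participant's
  transition rate, anchor count and activity level are multiplied by
  `1 − effect_size × 0.25`, and the daytime home weight by
  `1 + effect_size × 0.25` — i.e. a downward shift of `effect_size`
  reference SDs. Record volume scales with movement as
  `(rate / 8)^0.3`, so depressed participants also emit fewer GPS records.
  These directions (fewer location changes, fewer records, lower entropy
  under depression) are the signs the linear model should recover.
  No published value exists for the true effect size on any single
  mobility feature, so it is an explicit free parameter.
- **Heterogeneity** (`heterogeneity_sd`, default 0.5): lognormal
  multipliers `exp(σZ − σ²/2)` on every lifestyle parameter. At σ = 0 all
  non-depressed participants share one lifestyle; at σ ≈ 0.6 between-person
  variance dominates the depression shift, which is precisely what erases
  out-of-sample discrimination in heterogeneous cohorts.

### Sensing

Event-based sampling defaults: 403.57 records per tracked day (SD 250.72)
and 24.92 m radial GPS noise (per-axis SD = 24.92/√2), matching the sensing
characteristics the pipeline is designed for. A 5% per-day dropout
probability produces untracked days. Timestamps are strictly increasing;
one timezone offset per cohort (default 0) — day boundaries and the
22:00–06:00 home window only make sense in local time, and a single offset
avoids timezone ambiguity in synthetic data.

### Surveys and steps

Up to 3 sessions/day (1/2/3 with probabilities 0.15/0.35/0.50), each
administering 6 of the 17 items. Item endorsement is a logistic function of
the latent severity with item-specific intercepts (core items 0.35–0.47,
additional 0.48–0.68) and slope 0.07; slope 0 degenerates to a step
function, giving exact all-or-nothing endorsement for severity 0/1.
Depressed participants draw severity ~ U(0.60, 0.95), others U(0, 0.35);
with the ≥50%-endorsement presence rule this calibration yields ≥ 90%
agreement (empirically ≈ 100%) between the latent truth flag and the
scored ICD-10 label. Daily steps are
`activity × (0.4 + 0.6 × day_distance / mean_distance)` with 8% lognormal
noise, so steps track movement and zero activity gives zero steps.

### Demographics

Six categorical attributes (gender, age band, education, urbanicity,
sexual orientation, ethnicity) drawn independently of lifestyle from
configurable distributions shaped like a self-selected U.S. app cohort.
An optional coupling map (attribute level → lifestyle multipliers) exists
so that confounded scenarios (e.g. rural → sparser anchors) can be
constructed; it is off by default so subgroup analyses can be tested under
a true null.

## Scoring conventions

Presence across repeated prompts uses a ≥ 50% endorsement rule (robust to
single bad days; the aggregation cadence of real assessment apps is not
public, so this is fixed and documented). Severity grading: mild = 2 core +
2–3 additional; moderate = ≥ 2 core + ≥ 4 additional; severe = 3 core +
≥ 4 additional; the binary model target is severity ≥ mild. Unscoreable
windows (no assessed core or no assessed additional symptom) are explicit
results, never silent negatives, and such participants are removed by the
survey filter. Burden ratings are carried but unused in classification.

## Feature registry

The daily registry has exactly 33 features and the period registry exactly
38 (see `feature_registry.json` written by every run); daily features are
aggregated with mean/min/max/sample-SD over tracked days, 38 + 132 = 170.
Conventions, chosen once and applied uniformly:

- distances: haversine, Earth radius 6,371,000 m;
- "time spent" proportions are record-count weighted (sampling is
  event-based, so the record stream is already movement-weighted; a
  duration-weighted variant would need dwell imputation);
- location changes count label changes between consecutive *non-noise*
  records — noise records are transparent, so GPS jitter does not create
  movement;
- sample (n−1) SD everywhere; SD of one day is missing;
- ε = 1e-10 inside all logarithms; speed uses a 1 s gap floor; stationarity
  threshold 0.15 m/s;
- home ties break by night-record count, then total count, then lower
  cluster id; with no night records the most-populated cluster is home;
  with no clusters at all, home-dependent features are missing and are
  mean-imputed downstream;
- circadian movement is the log Lomb–Scargle energy of latitude and
  longitude in the 23.5–24.5 h period band. Note that over a 14-day window
  the spectral peak has a Rayleigh width of ≈ 1.7 h, so band energies in a
  1 h sweep are dominance-comparable but not sharply separable — tests
  assert dominance of the 24 h band, not a fixed energy fraction;
- DBSCAN labels are canonically renumbered by first-occurring member, so
  labelings are stable under record-order permutation.

## Modelling conventions

Mean imputation and (logistic only) z-standardization are fit on the outer
training fold and applied to its test fold; feature selection (top-k by
absolute point-biserial correlation, k = 50 by default) and hyperparameter
tuning (3-fold stratified grid search, argmax mean AUC, ties to the earlier
grid entry) likewise see training data only. The published pipelines this
mirrors do not disclose their selection method or grids; the filter method
and the shipped grids (logistic: L1/L2 × 7-point log-spaced C; forest:
trees {100,500} × depth {3,10,∞} × features {√p, 0.3p}; XGBoost: learning
rate {0.03,0.1,0.3} × depth {2,4,6} × rounds {50,200} × subsample
{0.8,1.0}) are explicit stand-ins. AUC uses class-1 probabilities for all
three families; the summary is the mean over outer splits with a
normal-theory 95% half-width (1.96·sd/√n). All Monte-Carlo split seeds,
fold seeds and estimator seeds derive deterministically from
(master seed, indices) via `SeedSequence`, so identical (data, spec, seed)
reproduce identical results bit-for-bit.

Subgroup evaluation of the global model computes AUC per outer split over
the subgroup's test-set members (both classes required) and averages over
qualifying splits, keeping the unit of analysis identical to the global
metric; pooling predictions across splits would mix models and is not the
default. Residualization subtracts per-class column means (OLS on a binary
regressor), guaranteeing zero label correlation; the residual matrix is
z-scored before k-means because the features span wildly different scales.
k-means uses 10 seeded restarts per k; clusters must exceed 100 members
(50 for subgroups, as stated boundaries: ≥ 50 / > 100) to be modelled.

## Problem sizes

Cohort-scale experiments and the acceptance script run at a scaled sensing
rate of 96 records/day (SD 48) with the 1000-record inclusion threshold
scaled by the same factor (240); the homogeneous/heterogeneous contrast is
a property of lifestyle variance, not sampling rate, and this size keeps a
full pair (n = 300 + 1500, 10 outer splits) around 80 s. The Gaussian
closed-form check uses n = 2000 and 25 outer splits; the subgroup-null
check uses n = 700 with 30 outer splits.

## What the simulator does and does not establish

Passing tests show that the pipeline recovers planted effects with the
correct signs, that its fold hygiene admits no leakage, and that the
homogeneity/heterogeneity contrast emerges from lifestyle variance alone.
The generator does **not** model road networks, multi-city travel,
seasonal or weekday-specific schedules beyond the shared hourly template,
phone-off gaps beyond i.i.d. daily dropout, GPS accuracy heteroscedasticity,
or measurement properties of real symptom surveys (item response styles,
missingness correlated with mood). Absolute AUC levels on synthetic cohorts
are therefore not predictions of real-data performance; only the ordering
and qualitative structure carry over.

## Known limitations

- There is no single canonical 33/38 feature list in the field; the shipped
  registries pin the counts, document every column, and are data-driven, so
  an alternative registry can be dropped in without touching the
  aggregation code.
- The region filter on synthetic data is a bounding-box stand-in for a
  country filter; urbanicity is a binary urban/rural stand-in for a
  multi-level urban influence index.
- Exactly reproducing published real-data AUCs is out of scope by design:
  the raw study data is not available, and the simulator's effect size is a
  free parameter.
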