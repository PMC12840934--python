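# Methods

This note documents the models and procedures implemented in `basalwatch`,
the parameter choices that matter, what the synthetic cohorts emulate (and
do not), and the numerical conventions a reimplementation would need.

## Setting and data model

The unit of observation is the resident-day. Four vital-sign channels are
modeled — body temperature (°C), oxygen saturation (%), heart rate
(beats/min), electrodermal activity (µS) — alongside static demographics
(age, sex, Barthel index of functional independence) and daily community
signals: pollutant concentrations (NO₂, O₃, PM₁₀, PM₂.₅, SO₂), meteorology,
and search-volume indices for symptom keywords. Clinician labels classify
each resident-day as healthy or infected, with infected days categorized as
acute respiratory infection (ARI), urinary tract infection (UTI), or a
heterogeneous "other" class (mainly skin/soft-tissue infections). Tables
travel as long-format CSV with ISO dates; the in-memory containers are
pandas DataFrames throughout.

## Synthetic cohort generator

Real data of this kind are private, so the generator is a first-class,
tested component that plants every effect the analysis is supposed to
recover and logs it in a `truth` table written to a separate file the
pipeline stages never read.

Defaults are the reference campaign conditions: 60 residents observed daily for
500 days (~16.5 months; tests and the acceptance script use 350-day
horizons to keep runtimes in minutes); mean age 87.6; a mean of 152/60 ≈ 2.53
infection events per resident with a category mix of 48:54:50 over
ARI/UTI/other; 80% missingness per channel; a 7-day prodrome shifting
TEMP +0.8 °C, SpO₂ −3%, BPM +8, EDA +0.5 µS; community search pulses leading
facility events by 6 days.

Specific choices:

- **Baselines.** Per-resident channel means are drawn around population
  norms (36.6 °C, 96%, 72 BPM, 2.0 µS) with between-resident SDs of
  (0.30, 1.5, 8.0, 0.50) and within-resident daily SDs of
  (0.25, 1.0, 5.0, 0.30). The between/within ratio is what makes population
  thresholds useless and the personalized quantizer necessary.
- **Event counts.** Events per resident follow a shifted geometric
  distribution with mean `infection_rate`. At the default rate this single
  parameter reproduces both a ~28% never-infected fraction and ~3.5 events
  per affected resident — the recurrence structure of the reference cohort.
  Diagnosis dates are placed uniformly with rejection to enforce a
  configurable minimum spacing (default 25 days), so washout-merged and
  washout-separated timelines can both be constructed.
- **Prodrome.** Vitals in `[T0 − prodrome_days, T0)` are shifted by the
  per-channel effect plus a jitter of 10% of the effect magnitude;
  intervals extending before the horizon start are truncated. Days outside
  prodrome intervals are untouched.
- **Missingness.** Each resident-day-channel cell is masked independently
  with probability centred on `missing_rate` on the log-odds scale and
  shifted by a weekend factor (odds ×1.5 on weekends, compensated on
  weekdays so the overall rate is preserved). Masking never conditions on
  health status, so the mechanism is missing-at-random given the
  operational covariate — emulating nursing-shift-driven gaps — and a
  chi-square contingency test on generator output confirms independence
  from infection labels.
- **External signals.** Search keywords carry triangular pulses (default
  width 1 day, amplitude 25 on a baseline of 50 with noise SD 3) placed
  `external_lead_days` before each facility event of their associated
  category; respiratory keywords respond to ARI, urinary keywords to UTI, a
  general-malaise keyword to all (half amplitude for "other" events, which
  have a weak digital footprint). Pollutants follow an annual sinusoid plus
  noise, elevated on the day of and before each ARI event in proportion to
  `pollution_ari_coupling`. Keywords are abstract (`kw_resp_1`, `kw_uti_1`),
  not natural-language terms.

What the generator does *not* emulate: within-facility transmission
networks, seasonal clustering of infection onset, autocorrelated vital-sign
noise, device-specific measurement error, or missingness that depends on
health status (MNAR). Pipeline results on synthetic cohorts therefore
demonstrate *correct recovery of planted structure under the stated
assumptions*, not expected performance on real clinical data.

## Gap-limited imputation

A run of >`max_gap` (default 4) consecutive missing days splits a
resident-channel series into independent segments; those days are never
imputed, and leading/trailing nulls (no observed anchor on both sides) are
likewise never filled. Within segments, three protocols fill nulls:

- **MEAN** — the per-channel mean of observed training-row values (global
  scope by default; per-resident scope available). Time interpolation is
  deliberately not used.
- **kNN** — sklearn's `KNNImputer` (k = 5, Euclidean) on same-day wide
  vectors (the four channels plus age and Barthel index), z-standardized
  with training statistics.
- **MICE** — sklearn's `IterativeImputer` (chained regressions, 10
  iterations) with posterior sampling; 5 draws are pooled by mean into a
  single completed table. Rubin-style variance propagation is out of scope.

All statistics are fitted only on rows designated as training data, so
held-out residents cannot leak into the imputation model; the suite asserts
that corrupting non-training rows leaves training-row fills unchanged.

**Test purity.** No evaluated prediction may rest on imputed values. The
window builder can emit two aligned feature sets — one aggregating all
non-null cells (used to train) and one aggregating observed cells only
(used to score test folds). `assert_test_purity` audits any sample table
against its fold assignment and lists violators.

## The basal quantizer

For each resident × channel the module keeps a history multiset
H_t = {x₁, …, x_{t−1}} of that resident's previous *healthy* values and its
empirical quartiles, recomputed exactly after each insertion (histories are
a few hundred points; the type-7 linear-interpolation estimator is used,
pinned by a brute-force oracle test). Each observation maps to

    Q = 1 (x ≤ q25) | 2 (q25 < x ≤ q50) | 3 (q50 < x ≤ q75) | 4 (x > q75)

with ΔQ the first difference of consecutive defined states (0 at the first
defined state — no predecessor, no fabricated transition). Conventions:

- Q is undefined until `min_history` = 4 values have been absorbed
  (quartiles of fewer points are degenerate); the value set {1,2,3,4} with
  ties to the lower bin.
- Days labeled infected are quantized but never absorbed into H_t, so the
  baseline cannot drift toward the pathological state. The gate is
  label-driven and switchable.
- The stream is causal: the reading at day t is unaffected by any later
  value, and null days yield undefined readings with no update.

Because quartile ranks are preserved by monotone affine maps, the (Q, ΔQ)
stream is identical for x and a·x + b (a > 0) — the property that decouples
the classifier from individual baselines, asserted over random series.

## Lead/Lag framework and sample construction

For an event diagnosed at T0 with anticipation horizon `lag`, the
prediction point is T_t = T0 − lag and the feature window is the closed
interval [T_t − lead, T_t]. The interval (T_t, T0] — overt pre-diagnostic
deterioration — is strictly excluded; the suite asserts bit-identical
feature vectors under arbitrary perturbation of that interval. Infected-day
runs of one resident merge into a single event unless separated by a
washout of ≥ 15 days; resident-days carrying two simultaneous diagnoses are
dropped as noisy labels before segmentation.

Features per window: mean/min/max of each vital channel, mean Q and last
ΔQ per channel, age, sex, Barthel index, and — per scenario — window mean
and window-end value of each external signal (POLLUTION adds pollutants and
meteorology, SOCIAL adds search indices, BASIC adds nothing). External
series can additionally be shifted forward ("lagged exposure") before
windowing.

Healthy prediction points are drawn uniformly (seeded) from days whose
windows stay ≥ washout days clear of every event of that resident, capped
at 5 per resident to bound imbalance; classes are then balanced by random
undersampling to the minority count. A window is skipped when it would
extend before the horizon (`skipped_boundary`) or contains fewer than
`min_window_obs` = 2 resident-days with any non-null vital
(`skipped_sparse`); a channel with no in-window data yields NaN aggregates,
which the boosted trees consume natively via default-direction splits. At
80% missingness a stricter per-channel minimum would discard most event
windows, which is why the validity rule is at the window level. Skip
counts satisfy emitted + skipped = attempted on every build.

## Modeling and evaluation

Both tasks use XGBoost (`tree_method="hist"`, single-threaded,
seed-deterministic). Folds come from scikit-learn's Stratified Group K-Fold
(k = 5, shuffled, seeded) grouped on resident identity — the
identity-leakage guard; every run asserts train/test resident disjointness.
Hyperparameters are tuned by seeded randomized search (depth 2–6, learning
rate 0.01–0.3 log-uniform, 50–400 trees, row/column subsampling 0.6–1.0)
scored by mean out-of-fold MCC, the objective of choice under class
imbalance since it weighs all four confusion quadrants; degenerate
single-class folds are skipped and logged. The search reuses the evaluation
folds (non-nested), so tuned scores carry a mild optimistic bias — a
deliberate simplicity trade-off, documented here.

Evaluation pools out-of-fold predictions and reports one-vs-rest
precision, recall (sensitivity), specificity and F1 per class, macro-F1,
and MCC — the four-quadrant formula for two classes, the Gorodkin
multi-category generalization otherwise (they coincide at k = 2, which is
tested). Zero-denominator rates are reported as NaN with an explicit flag,
never silently as 0. Rates are rounded only at presentation (half-up, two
decimals, the convention of printed clinical tables).

The lag sweep rebuilds samples for every (lead, lag) cell, tunes and
evaluates each, and records per lag the maximum F1 over leads (infected
class for binary, macro for multiclass) with its argmax lead. Cells with
any class below 5 balanced samples, or fewer residents than folds, are
invalid and excluded from the maximum. Binary cells also record pooled
out-of-fold marginals so that permutation-null F1 bands can be
reconstructed without refitting.

## Attribution and feature selection

Attributions are exact TreeSHAP values computed by the xgboost booster
itself (`pred_contribs=True`), in raw-margin (log-odds) units; local
accuracy (attributions + base value = margin) is asserted per sample. They
are computed on out-of-fold samples only, pooled across folds, to avoid
conflating fit with signal. Global importance is the mean absolute
attribution; for the multiclass task the overall importance is the
unweighted mean of per-class importances (per-class columns available,
since averaging can hide class-specific signals). The Selected Feature Set
keeps features whose importance strictly exceeds a threshold — by default
1% of the total attribution mass, a relative rule that transfers across
scenarios; an absolute mode exists. Selection is monotone in the threshold
and errors (advising a lower threshold) rather than returning an empty set.

## Problem sizes and verification design

The test and acceptance cohorts use 60 residents × 350 days (or smaller),
chosen so the full suite runs in a few minutes on one CPU while keeping
per-cell sample counts in the hundreds. Verification is two-pronged:

- **Exact checks** — descriptive-summary arithmetic on the reference
  cohort counts; quantizer agreement with a brute-force sorted-history
  oracle on 1,000 random cases; metric agreement with enumeration oracles
  and an independent library implementation; causal-integrity and gap-rule
  scans.
- **Recovery checks (seeded, stochastic)** — a strong planted prodrome
  (TEMP +1.0 °C, SpO₂ −4%) must be detected out-of-fold with infected-class
  recall > 0.8 and MCC > 0.5, and must vanish (|MCC| < 0.15) on a null
  cohort; a planted 6-day community-signal lead must be the argmax of the
  SOCIAL-scenario lag sweep (±1 day) while every BASIC cell stays inside
  its permutation-null F1 band.

## Known limitations

- Synthetic validation only: passing recovery checks demonstrates pipeline
  correctness, not clinical performance; no real-data headline metrics are
  claimed.
- Non-nested tuning mildly inflates tuned out-of-fold scores (a nested
  switch is not provided).
- The basal history is expanding, not windowed or decaying; slow secular
  drift in a resident's physiology is absorbed into the baseline.
- MICE pools draws by mean; imputation uncertainty is not propagated into
  downstream inference.
- Probability calibration, ROC analysis, survival-style censoring, and
  hierarchical facility-level modeling are out of scope.
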