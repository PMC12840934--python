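# basalwatch

Early detection of infections in nursing-home residents from intermittently
sampled vital signs, personalized per-resident baselines, and community-level
context signals.

## The problem

Frail elderly residents decompensate quickly once an infection (acute
respiratory infection, urinary tract infection, skin/soft-tissue infection)
becomes clinically overt. Pathogen proliferation, however, perturbs vital
signs days before diagnosis — a prodrome that fixed population thresholds
("alert if T > 38 °C") miss, because inter-subject variability in this
population dwarfs the prodromal shift. Clinical monitoring is also sparse:
vitals are taken during nursing shifts, not continuously, leaving ~80% of
resident-day-channel cells unobserved.

`basalwatch` implements a full analysis pipeline for this setting, aimed at
biostatisticians and digital-epidemiology researchers who want to study (or
stress-test) prodrome-based early warning under realistic missingness:

- **Synthetic cohort generator** — residents with individual baseline vitals
  (TEMP, SpO₂, BPM, EDA), recurrent infection events with planted prodromal
  drift, operationally-driven (MAR) missingness, and community signals
  (search-volume keywords that *lead* facility events, pollutants coupled to
  respiratory events). Everything planted is recorded in a ground-truth table
  the pipeline never sees, so recovery is testable.
- **Gap-limited imputation** — mean / kNN / MICE protocols that only ever fill
  gaps of ≤ 4 days; longer gaps split a series into independent segments that
  are never bridged.
- **Basal module** — the personalized quantizer. For each resident × channel
  it maintains an expanding healthy-history H_t and its empirical quartiles
  (q25, q50, q75), mapping each observation to a categorical state
  `Q ∈ {1,2,3,4}` and its day-to-day difference `ΔQ = Q_t − Q_{t−1}`.
  The (Q, ΔQ) stream is invariant to affine rescaling of the raw series, so a
  classifier learns a *universal deviation signature* rather than memorizing
  identities. Infected days are quantized but never absorbed into H_t.
- **Lead/Lag windowing** — for an event diagnosed at T0 and anticipation
  horizon `lag`, the prediction point is T_t = T0 − lag and features come
  exclusively from `[T_t − lead, T_t]`; everything in `(T_t, T0]` is excluded
  (bit-level causal integrity, enforced by tests). Infected-day runs separated
  by < 15 days are merged (washout); class balance by random undersampling.
- **Modeling** — XGBoost classifiers for a binary screen (healthy/infected)
  and a multiclass triage (healthy/ARI/UTI/other), tuned by seeded randomized
  search maximizing the out-of-fold Matthews correlation coefficient under
  Stratified **Group** K-Fold on resident identity (no resident ever spans a
  train/test split). Test folds are scored on imputation-free feature vectors.
- **Interpretation** — exact TreeSHAP attributions (local accuracy asserted),
  mean-|SHAP| rankings, and threshold-based feature selection.
- **Evaluation** — per-class precision/recall/specificity/F1, binary and
  generalized (Gorodkin) MCC, scenario-comparison tables, and a max-F1-per-lag
  sweep that finds the anticipation horizon at which each data scenario
  (BASIC vitals-only, POLLUTION, SOCIAL) performs best.

## Worked example

Simulate the default study-scale cohort (60 residents, 350 days, 80%
missingness, prodromal drift before each of ~150 infection events), impute,
and fit the binary screen at a 2-day anticipation horizon with a 7-day
observation window:

```python
import basalwatch as bw

spec = bw.CohortSpec(n_residents=60, n_days=350, seed=11)
cohort = bw.simulate(spec)
cohort.vitals = bw.impute(cohort.vitals, bw.ImputationConfig(method="MEAN", seed=0))

results = bw.InfectionModel.from_cohort(
    cohort, lead=7, lag=2, scenario="BASIC",
    config=bw.ModelConfig(search_iterations=5, seed=0),
).fit()
print(results.summary())
print(results.importances().nsmallest(5, "rank").to_string(index=False))
```

```
InfectionModel results — task=binary, scenario=BASIC, features=23 (FULL)
params: max_depth=2, learning_rate=0.223, n_estimators=335, subsample=0.843, colsample_bytree=0.892
   class  precision  recall  specificity   f1  support
 HEALTHY       0.86    0.72         0.88 0.78      138
INFECTED       0.76    0.88         0.72 0.81      137
MCC: 0.6088  macro-F1: 0.7987  n: 275
task=binary  scenario=BASIC  feature_set=FULL  lead=7  lag=2  seed=0

   feature  mean_abs_shap  rank
  TEMP_max       2.388004     1
Q_EDA_mean       1.186270     2
  SPO2_min       1.132803     3
Q_BPM_mean       1.118256     4
   EDA_max       0.885507     5
```

Reading this: out of 275 out-of-fold predictions (scored only on observed,
never-imputed data, pooled over 5 resident-grouped folds), the screen catches
88% of infection windows two days before diagnosis at 72% specificity
(MCC 0.61). The attribution ranking recovers the physiology that was planted:
the window temperature maximum dominates, with personalized quantile states
(`Q_*_mean`) and the SpO₂ minimum close behind — i.e., the model is reacting
to prodromal deviation from each resident's own baseline, not to identity.

A command-line front end mirrors the library
(`basalwatch simulate / impute / basal / build / fit / sweep / explain`);
see `basalwatch --help`.

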