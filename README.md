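# wearisk

Predicting mental-illness onset from consumer wearable data and routine
medical examinations.

People who go on to initiate psychiatric care often show behavioural changes
— disrupted sleep rhythms, napping, altered activity — months before their
first consultation. `wearisk` implements an end-to-end pipeline that turns
raw Fitbit-style sleep/activity logs, annual health-exam records, and
insurance-claims events into a monthly risk model of mental-illness onset,
together with the interpretability analysis needed to read a boosted-tree
model feature by feature. Because real claims-linked wearable databases are
proprietary, the package ships a first-class synthetic cohort generator that
emulates the raw tables (with configurable pre-onset effects), so the entire
pipeline is testable and reproducible offline.

It is aimed at biostatisticians and digital-phenotyping researchers who want
a tested reference implementation of:

* **Outcome labelling from claims.** Onset is the first month in which a
  subject initiates *both* a psychotropic prescription (ATC N05B/N05C/N06A)
  and a psychiatric-visit procedure code (I002/I002-2); subjects whose two
  first events fall in different months are excluded as discordant, as are
  subjects with onset before, during a gap in, or within 3 months of
  starting device linkage.
* **Observation windows.** Three consecutive calendar months, each with ≥ 15
  device-linked days; label = onset in the following month. Negative
  subjects contribute every qualifying sliding window, onset subjects only
  the window ending the month before onset.
* **Sleep-rhythm metrics.** Sleep Regularity Index
  `SRI = (1/1440·P) Σ_pairs Σ_t 1[s(d,t) = s(d+1,t)]` over consecutive
  linked day-pairs on a 1-minute epoch grid; social jetlag = circular
  |mid-sleep(weekend) − mid-sleep(weekday)| in minutes; chronotype
  `MSFsc = MSF − (SDF − SDweek)/2` when free-day sleep exceeds workday
  sleep; circular clock means throughout.
* **Risk model.** XGBoost binary classifier with weighted logloss
  (`w_i = class_weight` for positives), `eta = 0.05`, `max_depth = 2`,
  `min_child_weight = 16`, `colsample_bytree = 0.8`, `class_weight = 10`,
  `nrounds = 137`, evaluated by repeated stratified **group** 10-fold CV
  (all windows of a subject stay in one fold) with the per-repeat AUC
  computed on pooled out-of-fold predictions.
* **Split-threshold interpretability.** For each high-gain feature, the
  *mode split* (most frequent branch threshold in the ensemble) and its
  *cover* (fraction of that feature's branches using it), then a two-sided
  Fisher exact comparison of onset rates below vs at-or-above the mode
  value, optionally conditioned on parent-path branch conditions.

## Worked example

```python
import wearisk as wr

gen = wr.GeneratorConfig(n_subjects=300, onset_rate=0.05, seed=1)
cohort = wr.generate_cohort(gen)          # six raw CSV-shaped tables
features, report = wr.build_features(cohort)
print(report["n_windows"], "windows,", int(features["label"].sum()), "positive")

X, y, groups = wr.feature_matrix(features)
cv = wr.repeated_group_cv(X, y, groups, wr.ModelConfig(n_folds=5, n_repeats=3, seed=0))
print(f"mean merged-fold AUC {cv.mean_auc:.3f} (SD {cv.sd_auc:.3f})")

booster = wr.fit_boosted_model(X, y, wr.ModelConfig(seed=0))
for row in wr.interpretability_report(booster, X, y, top_k=3):
    c = row.comparison
    print(f"{row.feature}: mode split {row.mode_value:.3g} "
          f"(cover {row.cover:.0%}, {row.n_mode}/{row.n_splits}); "
          f"onset {c.prop_low:.2%} below vs {c.prop_high:.2%} at/above, "
          f"p={c.p_value:.3g}")
```

Output (exact numbers depend on the seeds shown):

```
2532 windows, 21 positive
mean merged-fold AUC 0.938 (SD 0.012)
log_count.sleep2: mode split 23 (cover 78%, 28/36); onset 3.18% below vs 0.20% at/above, p=6.66e-09
notMainSleep.minutes1: mode split 3 (cover 93%, 27/29); onset 0.06% below vs 2.42% at/above, p=2.32e-09
notMainSleep.minutes3: mode split 3.82 (cover 71%, 12/17); onset 0.21% below vs 2.55% at/above, p=2.33e-07
```

Read: the fitted ensemble most often splits second-month sleep-linkage days
at 23; windows whose subject linked fewer than 23 sleep days in the middle
month carry a ~16× higher onset rate (people stop wearing the device to bed
before onset), and windows with more than ~3 minutes of daily non-main sleep
(napping) in months 1 and 3 are likewise flagged high-risk — both directions
match the injected pre-onset effects.

The same stages are scriptable from a shell:

```bash
wearisk simulate --seed 1 --n-subjects 300 --out raw/
wearisk build    --in raw/ --out windows.csv --min-linked-days 15
wearisk train    --in raw/ --seed 0 --out results/
wearisk interpret --model results/model_dump.json \
                  --features results/features.csv --top-k 10 --out interpret.json
```

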