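# Methods

This note documents the models and procedures implemented in `wearisk`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Study design

The unit of analysis is the *observation window*: three consecutive calendar
months of wearable data for one subject, each month with at least
`min_linked_days` (default 15) device-linked days, paired with the nearest
medical exam dated at or before the end of the third month, and labelled by
whether mental-illness onset occurs in the month that follows. A linked day
is any day with at least one sleep session or one activity record; the two
stream-specific day counts are also kept separately because they enter the
feature set (`log_count.sleep`, `log_count.active`).

Onset is a claims construct: the first month in which a subject initiates
*both* a psychotropic prescription (ATC classes N05B hypnotics, N05C
anxiolytics, N06A antidepressants) and a psychiatric-visit procedure code
(I002, I002-2). Requiring the conjunction guards against hypnotics
prescribed around, e.g., surgery; requiring the two first-events to share a
month excludes ambiguous histories (`excluded_discordant`). Subjects with
onset before device linkage, during a linkage gap, or within three months of
first linkage are excluded, since no labelled pre-onset window can exist for
them.

Negative subjects contribute **every** qualifying sliding window (windows
overlap; a fully linked subject observed for M months yields M−3 of them,
because a window is only emitted while the following month is still
observed). Onset subjects contribute exactly one window — the one ending the
month before onset — so the positive class is never diluted by the same
subject's earlier, healthy windows. Disjoint (non-overlapping) windows are
supported as an option.

## Sleep-rhythm metrics

All metrics work on session-level records with Fitbit field names. A session
is assigned to the calendar day containing the midpoint of its asleep
interval `[startTime + minutesToFallAsleep, startTime + timeInBed −
minutesAfterWakeup)`; this keeps a Friday-night sleep that ends Saturday
morning classified as a free-day (weekend) sleep. Weekdays are Mon–Fri,
weekends Sat–Sun; holidays are not modelled.

* **Sleep Regularity Index.** Sessions are rasterised onto a 1-minute
  epoch grid (both main and non-main sleep count as sleep; brief intra-sleep
  wake is ignored at grid level). For a month,
  `SRI = Σ_pairs Σ_{t=1..1440} 1[s(d,t)=s(d+1,t)] / (1440 · #pairs)`
  over consecutive day-pairs with both days linked and inside the month, on
  the [0, 1] scale. One such pair suffices; months without any pair are
  missing. A day linked through the activity stream but without sleep
  records is a legitimate all-wake day for the grid.
* **Social jetlag** (`SC_lag`): the circular absolute difference, in
  minutes (≤ 720), between the circular-mean mid-sleep clock times of
  weekday and weekend main sleeps of the month.
* **Chronotype** (`MSFsc`): mid-sleep on free days corrected for sleep
  debt: `MSFsc = MSF − (SDF − SDweek)/2` when `SDF > SDW`, else `MSF`,
  with `SDweek = (5·SDW + 2·SDF)/7`; durations are mean main-sleep
  `minutesAsleep` per day class.
* **Monthly aggregates**: plain means over days with a main sleep for the
  duration/stage fields, the count of non-main sessions, the mean daily
  non-main sleep minutes over sleep-linked days, the number of sleep-linked
  days, and the circular-mean bedtime.

Clock-valued features (bedtime, chronotype) are exported to the learner as
minutes elapsed since 18:00, which is continuous and monotone across the
plausible 18:00→12:00 band and avoids the midnight discontinuity of a raw
hh:mm encoding. How such features are best encoded is genuinely open; raw
clock minutes remain available (`clock_encoding="clock"`).

## Risk model

An XGBoost binary-logistic ensemble with per-instance weights —
`class_weight` (default 10) for positive windows, 1 otherwise — which for
cross-entropy is mathematically identical to a weighted-logloss objective
and portable across boosting libraries. Defaults: `eta 0.05`, `max_depth 2`,
`min_child_weight 16`, `colsample_bytree 0.8`, `nrounds 137`,
`base_score 0.5`, `tree_method hist`, single thread. Missing values are
left as NaN and routed natively by the trees; nothing is imputed and
features are not scaled (trees are scale-free). A grid-search helper
selects `max_depth` / `min_child_weight` / `colsample_bytree` /
`class_weight` by mean merged-fold AUC, breaking ties toward the simpler
model (smaller depth, then larger `min_child_weight`); `select_nrounds`
picks the boosting-round count by early stopping (patience 20) on one
group-held-out fold.

Evaluation is **repeated stratified group k-fold CV** (defaults 10×10).
All windows of a subject share a fold, so no identity leaks between training
and validation. Fold assignment is deterministic: subjects are shuffled by
seed, stably sorted into (positive, negative) strata ordered by window
count, and snake-assigned across folds — positives land within one of each
other per fold and total window counts stay balanced. Per repeat, the
out-of-fold predictions are pooled and a single rank-based (Mann–Whitney,
tie-corrected) AUC computed; the mean and SD (ddof=1) across repeats are
reported. Pooled out-of-fold AUC is known to be a conservative estimator
with very few positives (see the null-calibration subsection below).

Downstream statistics: the ROC operating point closest (Euclidean) to
(0, 1) with its probability cutoff; per-class Gaussian KDEs of the predicted
probability with boundary reflection at 0 and 1 so each curve integrates to
~1 despite the pile-up of predictions near zero (a degenerate zero-variance
class falls back to a narrow Gaussian bump); and probability-threshold risk
grouping (high group = predicted probability ≥ threshold) compared by
Fisher's exact test.

**Fisher's exact test** is implemented exactly: two-sided p = the sum of
hypergeometric point probabilities, over all tables with the observed
margins, not exceeding the observed table's probability within relative
tolerance 1 + 1e-7 (the standard convention). Computation uses exact
big-integer binomials whenever the table support is ≤ 4096 (always true
when one margin is small, as here, where the onset margin is ~24) and a
log-gamma formulation otherwise. scipy's implementation serves as an
independent cross-check in the tests, never as the implementation.

## Split-threshold interpretability (mode split / cover)

Boosted trees with interactions admit no single per-feature effect
direction, so the fitted ensemble is read from its JSON tree dump. For each
feature: collect the multiset of branch thresholds used anywhere in the
ensemble; the **mode split** is its most frequent value (ties resolve to
the smallest; equality is exact on the dump values, with optional rounding)
and **cover** = multiplicity / total branches on that feature. The training
windows with the feature non-missing are then split at the mode value
(below vs at-or-above, the at-or-above side matching the tree's "no"
branch) and onset rates compared by the two-sided Fisher test. A cover near
100% indicates the ensemble repeatedly re-used one changepoint — a
monotone, interaction-free relationship; low cover flags features whose
optimal threshold moves with context. For those, `conditional_path_split`
re-runs the grouping only on rows satisfying the branch's parent-path
conditions (e.g. all branches on a feature may sit under
`(log_count.sleep2 ≥ 30) = TRUE`), with rows failing or missing a condition
dropped, mirroring how the tree actually routes records. Gain importance is
the per-feature sum of split gains, normalised to fractions.

## Synthetic cohort generator

The generator emulates the five raw tables of a claims-linked wearable
database: per-event sleep sessions, daily activity, daily resting heart
rate, annual exams (including the previous calendar year, so early windows
find an exam within the 24-month lookback), and claims events, plus a
subjects table. Defaults define the package's study conditions: 5,000
subjects over 2018-01..2018-12 (~9 sliding windows/subject), male fraction
0.713, age 45.9 (SD 9.1) years, BMI 23.2 (SD 3.3) kg/m², per-day linkage
probability 0.80 (sleep) / 0.85 (activity), and a 1% per-subject onset
probability over the year — comparable, per month, to the ~0.5% observed
over a multi-year observation period in real insured cohorts, while keeping
a stable absolute number of positives at the default size.

Subjects carry latent traits: base bedtime (23:30 ± 45 min across subjects),
a weekend bedtime delay (45 ± 20 min), base sleep duration (420 ± 30 min,
+30 on weekends), a *night-to-night* bedtime SD that itself varies across
subjects (lognormal around 30 min, sigma 0.4 — real cohorts mix very
regular and very irregular sleepers), REM/deep stage fractions (0.20/0.15
± 0.03), and a gamma-distributed nap rate (mean 2/month, shape 1, giving
the long tail of habitual nappers). Stage minutes always partition
`minutesAsleep`; `timeInBed` = fall-asleep + asleep + intra-sleep wake +
after-wake. All randomness flows through `numpy` Generators seeded as
(seed, subject index), so cohorts are reproducible subject-by-subject and
byte-identical across runs.

Onset subjects get a drug + visit claims pair in a month drawn uniformly
among months with ≥ 3 preceding months (top-up of linked days guarantees
the pre-onset window is eligible), and their three pre-onset months are
perturbed by `effect_sizes`, expressed in feature units. Defaults are about
half a between-subject SD each: +2 naps/month, −0.03 SRI (delivered as
extra nightly schedule jitter with σ ≈ 638·|ΔSRI| minutes, from the
linearisation ΔSRI ≈ 4σ/(√π·1440) for rigid interval shifts), +15 min
asleep, −8 min REM, −4 sleep-linked days (a multiplicative linkage factor
applied to the second pre-onset month only — device abandonment precedes
onset), +25 light-activity minutes (third pre-onset month only), and
subject-level exam shifts TG +30 mg/dl, GT +15 U/l, DRINK −1 category.
Directions follow what has been reported before onset in claims-linked
wearable data; magnitudes are the package's own choice, targeting a
moderately predictable cohort rather than a trivially separable one.

**What passing tests show, and what they do not.** The generator produces
independent subjects with Gaussian/gamma trait mixtures, stationary
schedules, and label-conditional shifts confined to the pre-onset window.
It does not emulate seasonal or secular trends, autocorrelated mood-driven
behaviour, device-model measurement error, informative (health-dependent)
adherence outside the injected linkage effect, or correlated exam
biochemistry. Pipeline results on this cohort therefore validate the
machinery — labelling, windowing, metrics, leakage-free CV, interpretability
— and effect-recovery in a favourable regime; they say nothing about the
predictive performance attainable on real populations.

## Numerical choices and degenerate inputs

* Epoch length 1 minute; sessions longer than 24 h are rejected.
* Circular means return missing on empty input or a zero resultant vector.
* Probabilities are clipped into (1e-15, 1−1e-15) with a warning before
  logloss evaluation; AUC and ROC require both classes; densities require
  ≥ 2 points per class.
* Threshold grouping uses ≥ for the high/risk side, matching the
  "more than or equal" table column convention; degenerate (empty) groups
  are flagged rather than tested.
* Exam lookback 24 months (configurable); beyond it the exam block is
  missing-valued but the window is kept.
* The per-feature split-threshold mode uses exact float equality on dump
  values (dumps are deterministic text); a rounding precision is available.

## Test-suite problem sizes and null calibration

Unit and property tests run on small constructed schedules and a
120-subject cohort. The end-to-end acceptance checks use the default
5,000-subject cohort (10×10 CV) for effect recovery and the class-weight
contrast, and a dedicated zero-effect cohort for the null check. The null
check runs at 3,000 subjects with an 8% event rate (~240 positives): the
pooled out-of-fold AUC estimator has sampling SD ≈ 1/√(12·n_pos), so at the
default ~50 positives a single-seed estimate scatters well beyond ±0.05
around 0.5 even though labels are independent of features by construction
(verified directly by per-feature distribution tests); with ~240 positives
the estimator is precise enough for the band to be informative. This is a
choice about estimator power, not about the property under test.

## Known limitations

* The exam block is cross-sectional and annual; no within-year dynamics.
* `log_count.sleep` counts days with any sleep session; cohorts whose naps
  are recorded without main sleeps would inflate it.
* Conditional-path analysis conditions on explicit (feature, direction,
  threshold) triples; it does not replay the ensemble's missing-value
  routing for rows with missing condition features (they are dropped).
* The CV fold count must not exceed the number of subjects; stratification
  balances positive subjects, not positive windows (identical here, since
  positives own one window each).
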