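"""Synthetic wearable + claims cohort generator.

Emulates the five raw tables the onset-prediction pipeline consumes — per-event
sleep sessions (Fitbit-like schema), daily activity, daily resting heart rate,
annual medical exams, and monthly claims events — for a configurable number of
insured subjects over a study period.  Subjects flagged for mental-illness
onset receive a claims pair (psychotropic prescription + psychiatric visit in
the same month) and configurable perturbations of their three pre-onset months
(more naps, less regular sleep, longer total sleep, less REM, fewer linked
days, more light activity, drinking habit, elevated TG/GT), so the downstream
model has a recoverable signal whose direction matches what is observed in
real claims-linked wearable cohorts.

All randomness flows through one seed; each subject draws from an independent
sub-stream keyed by (seed, subject index), so a cohort is reproducible
subject-by-subject.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._months import month_end, month_start, ym_range, ym_to_idx

__all__ = [
    "ConfigError",
    "SchemaError",
    "GeneratorConfig",
    "RawCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_EFFECT_SIZES",
    "EFFECT_FEATURES",
]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class SchemaError(ValueError):
    """A raw-cohort table does not match the expected schema."""


#: Features whose pre-onset shift can be injected, with the shift expressed in
#: the feature's own units (counts/month, SRI fraction, minutes, days, exam units).
EFFECT_FEATURES = frozenset(
    {
        "notMainSleep.counts",
        "SRI",
        "minutesAsleep",
        "remMinutes",
        "log_count.sleep",
        "lightlyActiveMinutes",
        "TG",
        "GT",
        "DRINK",
    }
)

#: Default pre-onset shifts: directions follow what claims-linked wearable
#: cohorts report before onset (more polyphasic sleep, less regular rhythm,
#: longer time asleep, less REM, fewer device-linked days, more light
#: activity, drinking habit and liver markers up).
#: Magnitudes are about half a between-subject SD each, giving a moderately
#: predictable cohort rather than a trivially separable one.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "notMainSleep.counts": 2.0,   # extra naps per month
    "SRI": -0.03,                 # target drop on the [0,1] scale
    "minutesAsleep": 15.0,        # minutes of extra nightly sleep
    "remMinutes": -8.0,           # minutes of REM lost per night
    "log_count.sleep": -4.0,      # fewer sleep-linked days (pre-onset month 2)
    "lightlyActiveMinutes": 25.0, # extra light-activity minutes (pre-onset month 3)
    "TG": 30.0,                   # mg/dl
    "GT": 15.0,                   # U/l
    "DRINK": -1.0,                # toward 1 = drinks every day
}

# A rigid nightly shift s ~ N(0, sigma^2) of the whole sleep interval lowers the
# day-pair concordance by about 2*E|s_d - s_{d+1}|/1440 = 4*sigma/(sqrt(pi)*1440),
# so a target SRI drop of |delta| maps to sigma ~= 638*|delta| minutes.
_SRI_JITTER_SCALE = 1440.0 * np.sqrt(np.pi) / 4.0  # ~638.1


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the package's documented study conditions."""

    n_subjects: int = 5000
    study_start: int = 201801
    study_end: int = 201812
    male_fraction: float = 0.713
    age_mean: float = 45.9
    age_sd: float = 9.1
    bmi_mean: float = 23.2
    bmi_sd: float = 3.3
    onset_rate: float = 0.01

    # adherence: per-day probability that a stream records anything
    sleep_linkage_prob: float = 0.80
    activity_linkage_prob: float = 0.85

    # sleep schedule; bedtimes are minutes after 18:00 (23:30 = 330)
    bedtime_mean: float = 330.0
    bedtime_subject_sd: float = 45.0
    bedtime_night_sd: float = 30.0
    weekend_bedtime_delay_mean: float = 45.0
    weekend_bedtime_delay_sd: float = 20.0
    sleep_duration_mean: float = 420.0
    sleep_duration_subject_sd: float = 30.0
    sleep_duration_night_sd: float = 45.0
    weekend_sleep_extra: float = 30.0
    rem_fraction: float = 0.20
    deep_fraction: float = 0.15
    #: between-subject spread of stage fractions (SD of a clipped normal)
    stage_fraction_sd: float = 0.03
    #: lognormal sigma of the per-subject night-to-night bedtime SD
    #: (mean preserved at bedtime_night_sd); real cohorts mix very regular
    #: and very irregular sleepers
    bedtime_night_sd_spread: float = 0.4
    nap_rate_per_month: float = 2.0
    #: gamma shape of the per-subject nap rate (mean nap_rate_per_month);
    #: shape 1 gives the long tail of habitual nappers seen in the wild
    nap_rate_dispersion: float = 1.0

    exam_missing_rate: float = 0.03

    #: minimum union linked days guaranteed in each of a positive subject's
    #: three pre-onset months, so every onset subject owns one valid window
    min_window_days: int = 15

    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("male_fraction", "onset_rate", "sleep_linkage_prob",
                     "activity_linkage_prob", "rem_fraction", "deep_fraction",
                     "exam_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.rem_fraction + self.deep_fraction > 0.9:
            raise ConfigError("rem_fraction + deep_fraction must leave room for light sleep")
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        try:
            n_months = ym_to_idx(self.study_end) - ym_to_idx(self.study_start) + 1
        except ValueError as exc:
            raise ConfigError(f"study_start/study_end: {exc}") from exc
        if n_months < 5:
            raise ConfigError(
                "study_end must be at least 4 months after study_start "
                f"(got {self.study_start}..{self.study_end})"
            )
        for name in ("age_sd", "bmi_sd", "bedtime_subject_sd", "bedtime_night_sd",
                     "weekend_bedtime_delay_sd", "sleep_duration_subject_sd",
                     "sleep_duration_night_sd", "nap_rate_per_month",
                     "stage_fraction_sd", "bedtime_night_sd_spread"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        unknown = set(self.effect_sizes) - EFFECT_FEATURES
        if unknown:
            raise ConfigError(
                f"effect_sizes has unknown feature keys: {sorted(unknown)}; "
                f"allowed: {sorted(EFFECT_FEATURES)}"
            )

    @property
    def months(self) -> list[int]:
        return ym_range(self.study_start, self.study_end)


SLEEP_COLUMNS = [
    "subject_id", "startTime", "isMainSleep", "timeInBed", "minutesAsleep",
    "minutesToFallAsleep", "minutesAfterWakeup", "deepMinutes", "remMinutes",
    "lightMinutes", "wakeMinutes",
]
ACTIVITY_COLUMNS = [
    "subject_id", "date", "steps", "veryActiveMinutes", "fairlyActiveMinutes",
    "lightlyActiveMinutes",
]
RHR_COLUMNS = ["subject_id", "date", "RestingHeartRate"]
EXAM_VALUE_COLUMNS = [
    "BMI", "SBP", "DBP", "TG", "HDL", "LDL", "AST", "ALT", "GT", "FBS",
    "HBA1C", "US", "UP", "SMOKE", "DRINK", "AMOUNT_DRINK", "FITNESS", "WALK",
]
EXAM_COLUMNS = ["subject_id", "exam_date"] + EXAM_VALUE_COLUMNS
CLAIM_KINDS = ("drug_N05B", "drug_N05C", "drug_N06A", "visit_I002", "visit_I002_2")
CLAIMS_COLUMNS = ["subject_id", "month", "kind"]
SUBJECT_COLUMNS = ["subject_id", "GENDER", "birth_year"]

_TABLE_SCHEMAS = {
    "subjects.csv": SUBJECT_COLUMNS,
    "sleep_sessions.csv": SLEEP_COLUMNS,
    "daily_activity.csv": ACTIVITY_COLUMNS,
    "daily_rhr.csv": RHR_COLUMNS,
    "exams.csv": EXAM_COLUMNS,
    "claims.csv": CLAIMS_COLUMNS,
}


@dataclass
class RawCohort:
    """The six raw tables a study extraction would produce."""

    subjects: pd.DataFrame
    sleep_sessions: pd.DataFrame
    daily_activity: pd.DataFrame
    daily_rhr: pd.DataFrame
    exams: pd.DataFrame
    claims: pd.DataFrame
    study_start: int = 0
    study_end: int = 0

    def validate(self) -> None:
        ids = set(self.subjects["subject_id"])
        for name in ("sleep_sessions", "daily_activity", "daily_rhr", "exams", "claims"):
            table = getattr(self, name)
            if len(table) and not set(table["subject_id"]).issubset(ids):
                raise SchemaError(f"{name}: unresolved subject_id foreign keys")
        if len(self.sleep_sessions):
            dup = self.sleep_sessions.duplicated(["subject_id", "startTime"])
            if dup.any():
                raise SchemaError("sleep_sessions: duplicate (subject, startTime) keys")
        if self.study_start and len(self.claims):
            months = self.claims["month"]
            if (months < self.study_start).any() or (months > self.study_end).any():
                raise SchemaError("claims: month outside study period")
        if len(self.claims):
            bad = set(self.claims["kind"]) - set(CLAIM_KINDS)
            if bad:
                raise SchemaError(f"claims: unknown kind values {sorted(bad)}")

    def equals(self, other: "RawCohort") -> bool:
        for f in ("subjects", "sleep_sessions", "daily_activity", "daily_rhr",
                  "exams", "claims"):
            a = getattr(self, f).reset_index(drop=True)
            b = getattr(other, f).reset_index(drop=True)
            if not a.equals(b):
                return False
        return self.study_start == other.study_start and self.study_end == other.study_end


def _round_minutes(x: np.ndarray) -> np.ndarray:
    return np.round(x).astype(np.int64)


def generate_cohort(config: GeneratorConfig) -> RawCohort:
    """Simulate a full raw cohort under *config*; deterministic given (config, seed)."""
    config.validate()
    months = config.months
    n_months = len(months)
    start_ts = month_start(config.study_start)
    end_ts = month_end(config.study_end)  # exclusive
    dates = pd.date_range(start_ts, end_ts - pd.Timedelta(days=1), freq="D")
    n_days = len(dates)
    day_month = np.asarray([ym_to_idx(d.year * 100 + d.month) for d in dates])
    day_month -= ym_to_idx(config.study_start)  # 0-based month index per day
    weekend = np.asarray([d.weekday() >= 5 for d in dates])  # Sat/Sun
    dates64 = dates.values.astype("datetime64[m]")

    eff = {**{k: 0.0 for k in EFFECT_FEATURES}, **config.effect_sizes}
    sri_jitter_sd = _SRI_JITTER_SCALE * abs(eff["SRI"])
    # linkage reduction in pre-onset month 2, as a multiplicative factor
    expected_days = 30.0 * config.sleep_linkage_prob
    linkage_factor = max(0.0, 1.0 + eff["log_count.sleep"] / max(expected_days, 1e-9))

    # annual exams exist for the year before the study too, so early windows
    # still find an exam within the lookback horizon
    study_years = sorted({ym // 100 for ym in months})
    exam_years = [study_years[0] - 1] + study_years
    year_months = {y: [ym for ym in months if ym // 100 == y] or
                   [y * 100 + m for m in range(1, 13)] for y in exam_years}

    subj_rows: list[tuple] = []
    claims_rows: list[tuple] = []
    exam_rows: list[list] = []
    sleep_parts: dict[str, list[np.ndarray]] = {k: [] for k in (
        "sid", "start", "main", "inbed", "asleep", "fall", "after", "deep",
        "rem", "light", "wake")}
    act_parts: dict[str, list[np.ndarray]] = {k: [] for k in (
        "sid", "day", "steps", "very", "fairly", "lightly")}
    rhr_parts: dict[str, list[np.ndarray]] = {k: [] for k in ("sid", "day", "rhr")}

    end_year = config.study_end // 100
    for i in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), i]))
        sid = i + 1
        gender = 1 if rng.random() < config.male_fraction else 2
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 20, 75))
        birth_year = end_year - int(round(age))
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 15, 45))
        subj_rows.append((sid, gender, birth_year))

        onset = rng.random() < config.onset_rate
        onset_rel = int(rng.integers(3, n_months)) if onset else -1
        pre = np.zeros(n_days, bool)      # pre-onset window months (3 of them)
        pre_m2 = np.zeros(n_days, bool)   # second pre-onset month
        pre_m3 = np.zeros(n_days, bool)   # third (closest to onset)
        if onset:
            pre = (day_month >= onset_rel - 3) & (day_month <= onset_rel - 1)
            pre_m2 = day_month == onset_rel - 2
            pre_m3 = day_month == onset_rel - 1
            claims_rows.append((sid, months[onset_rel],
                                CLAIM_KINDS[rng.integers(0, 3)]))
            claims_rows.append((sid, months[onset_rel],
                                CLAIM_KINDS[3 + rng.integers(0, 2)]))

        # --- linkage indicators, drawn per day per stream ---
        p_sleep = np.full(n_days, config.sleep_linkage_prob)
        if onset:
            p_sleep[pre_m2] *= linkage_factor
        linked_sleep = rng.random(n_days) < p_sleep
        linked_act = rng.random(n_days) < config.activity_linkage_prob
        if onset:
            # guarantee one valid positive window: top up union-linked days
            for m in range(onset_rel - 3, onset_rel):
                in_m = day_month == m
                union = linked_sleep | linked_act
                deficit = config.min_window_days - int(union[in_m].sum())
                if deficit > 0:
                    candidates = np.flatnonzero(in_m & ~union)
                    pick = rng.choice(candidates, size=min(deficit, len(candidates)),
                                      replace=False)
                    linked_sleep[pick] = True

        # --- main sleeps: one per sleep-linked day (midpoint falls on that day) ---
        d = np.flatnonzero(linked_sleep)
        nd = len(d)
        bed_base = rng.normal(config.bedtime_mean, config.bedtime_subject_sd)
        wk_delay = rng.normal(config.weekend_bedtime_delay_mean,
                              config.weekend_bedtime_delay_sd)
        dur_base = rng.normal(config.sleep_duration_mean,
                              config.sleep_duration_subject_sd)
        spread = config.bedtime_night_sd_spread
        night_sd = config.bedtime_night_sd * rng.lognormal(
            -0.5 * spread**2, spread)
        rem_frac = float(np.clip(
            rng.normal(config.rem_fraction, config.stage_fraction_sd), 0.05, 0.4))
        deep_frac = float(np.clip(
            rng.normal(config.deep_fraction, config.stage_fraction_sd), 0.05, 0.4))
        bed = (bed_base + wk_delay * weekend[d]
               + rng.normal(0.0, night_sd, nd))
        if onset and sri_jitter_sd > 0:
            bed = bed + rng.normal(0.0, sri_jitter_sd, nd) * pre[d]
        asleep = (dur_base + config.weekend_sleep_extra * weekend[d]
                  + rng.normal(0.0, config.sleep_duration_night_sd, nd))
        if onset:
            asleep = asleep + eff["minutesAsleep"] * pre[d]
        asleep = _round_minutes(np.clip(asleep, 180, 720))
        rem = asleep * rem_frac + rng.normal(0.0, 10.0, nd)
        if onset:
            rem = rem + eff["remMinutes"] * pre[d]
        rem = _round_minutes(np.clip(rem, 5, None))
        deep = _round_minutes(np.clip(
            asleep * deep_frac + rng.normal(0.0, 8.0, nd), 5, None))
        # keep the stage partition inside minutesAsleep
        over = rem + deep > asleep - 10
        rem[over] = np.clip(((asleep - 10) * rem / (rem + deep))[over], 0, None).astype(np.int64)
        deep[over] = np.clip((asleep - 10 - rem)[over], 0, None)
        light = asleep - rem - deep
        fall = _round_minutes(np.clip(rng.gamma(2.0, 5.0, nd), 0, 60))
        after = _round_minutes(np.clip(rng.gamma(1.5, 3.0, nd), 0, 30))
        wake = _round_minutes(np.clip(rng.normal(35.0, 12.0, nd), 0, 120))
        inbed = fall + asleep + wake + after
        # bedtime on the evening before day d: 18:00 of day d-1 = day d - 6 h
        start = dates64[d] - 360 + _round_minutes(bed)
        sleep_parts["sid"].append(np.full(nd, sid, np.int64))
        sleep_parts["start"].append(start)
        sleep_parts["main"].append(np.ones(nd, bool))
        for key, arr in (("inbed", inbed), ("asleep", asleep), ("fall", fall),
                         ("after", after), ("deep", deep), ("rem", rem),
                         ("light", light), ("wake", wake)):
            sleep_parts[key].append(arr)

        # --- naps (non-main sleeps) on sleep-linked days ---
        shape = config.nap_rate_dispersion
        subj_nap_rate = rng.gamma(shape, config.nap_rate_per_month / shape)
        nap_rate = np.full(nd, subj_nap_rate / 30.0)
        if onset:
            nap_rate = nap_rate + (eff["notMainSleep.counts"] / 30.0) * pre[d]
        nap_counts = rng.poisson(np.clip(nap_rate, 0, None))
        nap_days = np.repeat(d, nap_counts)
        nn = len(nap_days)
        if nn:
            nap_start_min = rng.integers(12 * 60, 16 * 60, nn)  # early afternoon
            nap_dur = rng.integers(20, 71, nn)
            nap_wake = rng.integers(0, 6, nn)
            sleep_parts["sid"].append(np.full(nn, sid, np.int64))
            sleep_parts["start"].append(dates64[nap_days] + nap_start_min)
            sleep_parts["main"].append(np.zeros(nn, bool))
            sleep_parts["inbed"].append(nap_dur + nap_wake)
            sleep_parts["asleep"].append(nap_dur)
            sleep_parts["fall"].append(np.zeros(nn, np.int64))
            sleep_parts["after"].append(np.zeros(nn, np.int64))
            sleep_parts["deep"].append(np.zeros(nn, np.int64))
            sleep_parts["rem"].append(np.zeros(nn, np.int64))
            sleep_parts["light"].append(nap_dur)
            sleep_parts["wake"].append(nap_wake)

        # --- daily activity & resting heart rate ---
        a = np.flatnonzero(linked_act)
        na = len(a)
        steps_base = rng.normal(8000.0, 1500.0)
        lightly_base = rng.normal(200.0, 40.0)
        steps = _round_minutes(np.clip(steps_base + rng.normal(0, 1200.0, na), 0, None))
        very = _round_minutes(np.clip(rng.normal(20.0, 10.0) + rng.normal(0, 6.0, na), 0, None))
        fairly = _round_minutes(np.clip(rng.normal(15.0, 8.0) + rng.normal(0, 5.0, na), 0, None))
        lightly = lightly_base + rng.normal(0, 30.0, na)
        if onset:
            lightly = lightly + eff["lightlyActiveMinutes"] * pre_m3[a]
        lightly = _round_minutes(np.clip(lightly, 0, None))
        act_parts["sid"].append(np.full(na, sid, np.int64))
        act_parts["day"].append(a)
        act_parts["steps"].append(steps)
        act_parts["very"].append(very)
        act_parts["fairly"].append(fairly)
        act_parts["lightly"].append(lightly)
        rhr_mask = rng.random(na) < 0.95
        r = a[rhr_mask]
        rhr_base = rng.normal(62.0, 5.0)
        rhr_parts["sid"].append(np.full(len(r), sid, np.int64))
        rhr_parts["day"].append(r)
        rhr_parts["rhr"].append(np.round(rhr_base + rng.normal(0, 2.0, len(r)), 1))

        # --- annual medical exams ---
        drink = int(rng.choice([1, 2, 3], p=[0.25, 0.35, 0.40]))
        if onset:
            drink = int(np.clip(drink + eff["DRINK"], 1, 3))
        for y in exam_years:
            ym = year_months[y][int(rng.integers(0, len(year_months[y])))]
            exam_date = pd.Timestamp(year=ym // 100, month=ym % 100, day=15)
            tg = float(rng.lognormal(np.log(100.0), 0.45))
            gt = float(rng.lognormal(np.log(35.0), 0.6))
            if onset:
                tg += eff["TG"]
                gt += eff["GT"]
            vals = {
                "BMI": round(bmi + rng.normal(0, 0.3), 1),
                "SBP": round(float(np.clip(rng.normal(120, 14), 80, 220))),
                "DBP": round(float(np.clip(rng.normal(75, 10), 40, 140))),
                "TG": round(tg),
                "HDL": round(float(np.clip(rng.normal(60, 14), 20, 150))),
                "LDL": round(float(np.clip(rng.normal(120, 30), 30, 300))),
                "AST": round(float(np.clip(rng.normal(24, 8), 5, 300))),
                "ALT": round(float(np.clip(rng.normal(25, 12), 5, 300))),
                "GT": round(gt),
                "FBS": round(float(np.clip(rng.normal(95, 12), 50, 300))),
                "HBA1C": round(float(np.clip(rng.normal(5.5, 0.45), 4.0, 12.0)), 1),
                "US": int(rng.choice([1, 2, 3, 4, 5], p=[0.90, 0.05, 0.03, 0.015, 0.005])),
                "UP": int(rng.choice([1, 2, 3, 4, 5], p=[0.90, 0.05, 0.03, 0.015, 0.005])),
                "SMOKE": 1 if rng.random() < 0.28 else 2,
                "DRINK": drink,
                "AMOUNT_DRINK": int(rng.choice([1, 2, 3, 4], p=[0.35, 0.35, 0.20, 0.10])),
                "FITNESS": 1 if rng.random() < 0.25 else 2,
                "WALK": 1 if rng.random() < 0.35 else 2,
            }
            miss = rng.random(len(EXAM_VALUE_COLUMNS)) < config.exam_missing_rate
            row = [sid, exam_date]
            for j, colname in enumerate(EXAM_VALUE_COLUMNS):
                row.append(np.nan if miss[j] else vals[colname])
            exam_rows.append(row)

    sleep_sessions = pd.DataFrame(
        {
            "subject_id": np.concatenate(sleep_parts["sid"]),
            "startTime": pd.DatetimeIndex(
                np.concatenate(sleep_parts["start"]).astype("datetime64[ns]")
            ),
            "isMainSleep": np.concatenate(sleep_parts["main"]),
            "timeInBed": np.concatenate(sleep_parts["inbed"]),
            "minutesAsleep": np.concatenate(sleep_parts["asleep"]),
            "minutesToFallAsleep": np.concatenate(sleep_parts["fall"]),
            "minutesAfterWakeup": np.concatenate(sleep_parts["after"]),
            "deepMinutes": np.concatenate(sleep_parts["deep"]),
            "remMinutes": np.concatenate(sleep_parts["rem"]),
            "lightMinutes": np.concatenate(sleep_parts["light"]),
            "wakeMinutes": np.concatenate(sleep_parts["wake"]),
        }
    ).drop_duplicates(["subject_id", "startTime"]).sort_values(
        ["subject_id", "startTime"], kind="stable").reset_index(drop=True)

    daily_activity = pd.DataFrame(
        {
            "subject_id": np.concatenate(act_parts["sid"]),
            "date": pd.DatetimeIndex(dates[np.concatenate(act_parts["day"])]),
            "steps": np.concatenate(act_parts["steps"]),
            "veryActiveMinutes": np.concatenate(act_parts["very"]),
            "fairlyActiveMinutes": np.concatenate(act_parts["fairly"]),
            "lightlyActiveMinutes": np.concatenate(act_parts["lightly"]),
        }
    )
    daily_rhr = pd.DataFrame(
        {
            "subject_id": np.concatenate(rhr_parts["sid"]),
            "date": pd.DatetimeIndex(dates[np.concatenate(rhr_parts["day"])]),
            "RestingHeartRate": np.concatenate(rhr_parts["rhr"]),
        }
    )
    exams = pd.DataFrame(exam_rows, columns=EXAM_COLUMNS)
    claims = pd.DataFrame(claims_rows, columns=CLAIMS_COLUMNS)
    if claims.empty:
        claims = pd.DataFrame({"subject_id": pd.Series(dtype=np.int64),
                               "month": pd.Series(dtype=np.int64),
                               "kind": pd.Series(dtype=object)})
    subjects = pd.DataFrame(subj_rows, columns=SUBJECT_COLUMNS)

    cohort = RawCohort(subjects, sleep_sessions, daily_activity, daily_rhr,
                       exams, claims, config.study_start, config.study_end)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: RawCohort, directory: str | os.PathLike) -> list[str]:
    """Write the six tables (plus a tiny period stamp) as CSV; returns file paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for fname, attr in (
        ("subjects.csv", "subjects"), ("sleep_sessions.csv", "sleep_sessions"),
        ("daily_activity.csv", "daily_activity"), ("daily_rhr.csv", "daily_rhr"),
        ("exams.csv", "exams"), ("claims.csv", "claims"),
    ):
        path = os.path.join(directory, fname)
        getattr(cohort, attr).to_csv(path, index=False)
        paths.append(path)
    with open(os.path.join(directory, "period.csv"), "w") as fh:
        fh.write("study_start,study_end\n")
        fh.write(f"{cohort.study_start},{cohort.study_end}\n")
    paths.append(os.path.join(directory, "period.csv"))
    return paths


def _read_checked(directory, fname: str, parse_dates=None) -> pd.DataFrame:
    path = os.path.join(directory, fname)
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface file context
        raise SchemaError(f"{fname}: unreadable CSV ({exc})") from exc
    missing = [c for c in _TABLE_SCHEMAS[fname] if c not in table.columns]
    if missing:
        raise SchemaError(f"{fname}: missing column {missing[0]!r}")
    if parse_dates:
        for col in parse_dates:
            table[col] = pd.to_datetime(table[col])
    return table


def read_cohort(directory: str | os.PathLike) -> RawCohort:
    """Read a cohort written by :func:`write_cohort`, validating each table's schema."""
    subjects = _read_checked(directory, "subjects.csv")
    sleep = _read_checked(directory, "sleep_sessions.csv", parse_dates=["startTime"])
    activity = _read_checked(directory, "daily_activity.csv", parse_dates=["date"])
    rhr = _read_checked(directory, "daily_rhr.csv", parse_dates=["date"])
    exams = _read_checked(directory, "exams.csv", parse_dates=["exam_date"])
    claims = _read_checked(directory, "claims.csv")
    if claims.empty:
        claims = pd.DataFrame({"subject_id": pd.Series(dtype=np.int64),
                               "month": pd.Series(dtype=np.int64),
                               "kind": pd.Series(dtype=object)})
    period_path = os.path.join(directory, "period.csv")
    study_start = study_end = 0
    if os.path.exists(period_path):
        period = pd.read_csv(period_path)
        study_start = int(period.at[0, "study_start"])
        study_end = int(period.at[0, "study_end"])
    cohort = RawCohort(subjects, sleep, activity, rhr, exams, claims,
                       study_start, study_end)
    cohort.validate()
    return cohort


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> GeneratorConfig:
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg
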