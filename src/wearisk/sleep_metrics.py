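"""Sleep-rhythm indices from session-level sleep logs.

Implements the monthly sleep feature block: the Sleep Regularity Index (SRI,
the concordance of minute-wise sleep/wake state between consecutive days),
social jetlag (circular distance between weekday and weekend mid-sleep),
sleep-debt-corrected chronotype (MSFsc), circular averages of clock times,
and plain monthly means of the per-session Fitbit fields.

Conventions
-----------
* A session is assigned to the calendar day containing the midpoint of its
  sleep interval ``[startTime+minutesToFallAsleep,
  startTime+timeInBed-minutesAfterWakeup)``.
* The sleep/wake state grid uses 1-minute epochs; both main and non-main
  sleep count as sleep.  Intra-sleep wake is ignored at the grid level.
* Weekday (work) days are Mon-Fri, weekend (free) days Sat-Sun, judged on
  the day the session is assigned to — so a Friday-night sleep ending
  Saturday morning is a free-day sleep.
* Clock times are handled as minutes of the day in ``[0, 1440)`` and all
  averaging/differencing is circular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._months import month_end, month_start, ym_range

__all__ = [
    "EpochGrid",
    "MonthlyScheduleSummary",
    "sessions_to_epochs",
    "sri_month",
    "social_jetlag_month",
    "chronotype_month",
    "circular_mean_clock",
    "circular_diff_minutes",
    "schedule_summary_month",
    "monthly_sleep_aggregates",
    "monthly_sleep_features",
    "clock_to_minutes_from_18",
    "SLEEP_FEATURES",
]

MINUTES_PER_DAY = 1440

#: monthly sleep feature block, Table-style names
SLEEP_FEATURES = [
    "notMainSleep.minutes", "notMainSleep.counts", "log_count.sleep",
    "timeInBed", "minutesAsleep", "minutesToFallAsleep", "minutesAfterWakeup",
    "deepMinutes", "remMinutes", "lightMinutes", "wakeMinutes",
    "startTime.sleep", "SC_lag", "chronotype", "SRI",
]


# ---------------------------------------------------------------------------
# circular clock arithmetic
# ---------------------------------------------------------------------------

def circular_mean_clock(times) -> float:
    """Angle-mean of clock times given as minutes of day; result in [0, 1440).

    Returns NaN for an empty input or a perfectly balanced (zero resultant)
    configuration, where the circular mean is undefined.
    """
    t = np.asarray(times, dtype=float)
    t = t[~np.isnan(t)]
    if t.size == 0:
        return float("nan")
    ang = t * (2 * np.pi / MINUTES_PER_DAY)
    z = np.exp(1j * ang).mean()
    if abs(z) < 1e-12:
        return float("nan")
    return float(np.angle(z) % (2 * np.pi) * (MINUTES_PER_DAY / (2 * np.pi)))


def circular_diff_minutes(a: float, b: float) -> float:
    """Shorter-way absolute difference between two clock times, <= 720 min."""
    if np.isnan(a) or np.isnan(b):
        return float("nan")
    d = abs(a - b) % MINUTES_PER_DAY
    return float(min(d, MINUTES_PER_DAY - d))


def clock_to_minutes_from_18(minutes_of_day: float) -> float:
    """Encode a clock time as minutes elapsed since 18:00.

    Maps the plausible bed/mid-sleep band 18:00 -> 12:00 (noon next day) onto
    the continuous range [0, 1440), removing the midnight discontinuity that a
    raw hh:mm encoding would put in the middle of the night.
    """
    if np.isnan(minutes_of_day):
        return float("nan")
    return float((minutes_of_day - 18 * 60) % MINUTES_PER_DAY)


# ---------------------------------------------------------------------------
# epoch grid
# ---------------------------------------------------------------------------

@dataclass
class EpochGrid:
    """Binary sleep/wake state per 1-minute epoch per calendar day."""

    start_date: pd.Timestamp           # first day of the grid (midnight)
    sleep: np.ndarray                  # bool, shape (n_days, 1440)
    linked: np.ndarray                 # bool, shape (n_days,)

    @property
    def n_days(self) -> int:
        return len(self.linked)

    def day_index(self, date) -> int:
        return (pd.Timestamp(date).normalize() - self.start_date).days

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


def _sleep_bounds_minutes(sessions: pd.DataFrame, origin: pd.Timestamp):
    """Start/end of each session's asleep interval, in minutes from *origin*."""
    start_min = (sessions["startTime"] - origin).dt.total_seconds().to_numpy() / 60.0
    lo = start_min + sessions["minutesToFallAsleep"].to_numpy(float)
    hi = start_min + (sessions["timeInBed"].to_numpy(float)
                      - sessions["minutesAfterWakeup"].to_numpy(float))
    return lo, hi


def sessions_to_epochs(
    sessions: pd.DataFrame,
    linked_days=None,
    start=None,
    end=None,
) -> EpochGrid:
    """Rasterise one subject's sessions onto a minute grid.

    A minute is asleep iff it falls inside the asleep interval of any session
    (overlaps union, no double counting).  ``linked_days`` marks days whose
    state is known (default: days owning at least one session by the midpoint
    rule); a linked day without sessions is an all-wake day.
    """
    if len(sessions):
        if (sessions["timeInBed"] > MINUTES_PER_DAY).any():
            raise ValueError("session timeInBed exceeds 24 h")
        t0 = sessions["startTime"].min().normalize()
        t1 = (sessions["startTime"]
              + pd.to_timedelta(sessions["timeInBed"], unit="m")).max().normalize()
    else:
        if linked_days is None or len(linked_days) == 0:
            raise ValueError("cannot build a grid from no sessions and no linked days")
        t0 = t1 = None
    if linked_days is not None and len(linked_days):
        ld = pd.DatetimeIndex(linked_days).normalize()
        t0 = min(t0, ld.min()) if t0 is not None else ld.min()
        t1 = max(t1, ld.max()) if t1 is not None else ld.max()
    if start is not None:
        t0 = min(t0, pd.Timestamp(start).normalize())
    if end is not None:
        t1 = max(t1, pd.Timestamp(end).normalize())

    n_days = (t1 - t0).days + 1
    total = n_days * MINUTES_PER_DAY
    diff = np.zeros(total + 1, dtype=np.int32)
    if len(sessions):
        lo, hi = _sleep_bounds_minutes(sessions, t0)
        lo = np.clip(np.round(lo).astype(np.int64), 0, total)
        hi = np.clip(np.round(hi).astype(np.int64), 0, total)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
    covered = np.cumsum(diff[:-1]) > 0
    grid = covered.reshape(n_days, MINUTES_PER_DAY)

    linked = np.zeros(n_days, dtype=bool)
    if linked_days is not None:
        for day in pd.DatetimeIndex(linked_days).normalize():
            idx = (day - t0).days
            if 0 <= idx < n_days:
                linked[idx] = True
    elif len(sessions):
        mid = np.round((lo + hi) / 2.0).astype(np.int64) // MINUTES_PER_DAY
        linked[np.clip(mid, 0, n_days - 1)] = True
    return EpochGrid(t0, grid, linked)


def sri_month(grid: EpochGrid, month: int, min_pairs: int = 1) -> float:
    """Sleep Regularity Index for one month, on the [0, 1] scale.

    SRI = fraction of minute epochs with identical sleep/wake state on
    consecutive linked days, over all consecutive linked day-pairs whose
    both days fall inside the month.  NaN when fewer than ``min_pairs``
    such pairs exist.
    """
    d0 = grid.day_index(month_start(month))
    d1 = grid.day_index(month_end(month))  # first day of next month
    lo, hi = max(d0, 0), min(d1, grid.n_days)
    if hi - lo < 2:
        return float("nan")
    days = np.arange(lo, hi - 1)
    pair_ok = grid.linked[days] & grid.linked[days + 1]
    if int(pair_ok.sum()) < min_pairs:
        return float("nan")
    a = grid.sleep[days[pair_ok]]
    b = grid.sleep[days[pair_ok] + 1]
    return float((a == b).mean())


# ---------------------------------------------------------------------------
# monthly schedule summary, social jetlag, chronotype
# ---------------------------------------------------------------------------

@dataclass
class MonthlyScheduleSummary:
    """Main-sleep schedule statistics for one subject-month."""

    midsleep_workdays: float   # circular clock minutes, NaN if absent
    midsleep_freedays: float
    dur_workdays: float        # SDW: mean main-sleep minutesAsleep, workdays
    dur_freedays: float        # SDF
    dur_week: float            # SDweek = (5*SDW + 2*SDF)/7
    n_workdays: int
    n_freedays: int


def _session_day_and_clock(sessions: pd.DataFrame):
    """Assigned day (normalized), mid-sleep clock minutes, bedtime clock minutes."""
    fall = sessions["minutesToFallAsleep"].to_numpy(float)
    span = (sessions["timeInBed"].to_numpy(float) - fall
            - sessions["minutesAfterWakeup"].to_numpy(float))
    mid = sessions["startTime"] + pd.to_timedelta(fall + span / 2.0, unit="m")
    day = mid.dt.normalize()
    mid_clock = (mid - day).dt.total_seconds().to_numpy() / 60.0
    start_clock = (
        sessions["startTime"] - sessions["startTime"].dt.normalize()
    ).dt.total_seconds().to_numpy() / 60.0
    return day, mid_clock, start_clock


def schedule_summary_month(sessions: pd.DataFrame, month: int) -> MonthlyScheduleSummary:
    """Summarise main sleeps of one subject assigned to days of *month*."""
    main = sessions[sessions["isMainSleep"]]
    if len(main) == 0:
        return MonthlyScheduleSummary(np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0)
    day, mid_clock, _ = _session_day_and_clock(main)
    in_month = (day >= month_start(month)) & (day < month_end(month))
    free = day.dt.weekday >= 5
    w = (in_month & ~free).to_numpy()
    f = (in_month & free).to_numpy()
    asleep = main["minutesAsleep"].to_numpy(float)

    msw = circular_mean_clock(mid_clock[w]) if w.any() else float("nan")
    msf = circular_mean_clock(mid_clock[f]) if f.any() else float("nan")
    sdw = float(asleep[w].mean()) if w.any() else float("nan")
    sdf = float(asleep[f].mean()) if f.any() else float("nan")
    if np.isnan(sdw):
        sdweek = sdf
    elif np.isnan(sdf):
        sdweek = sdw
    else:
        sdweek = (5.0 * sdw + 2.0 * sdf) / 7.0
    return MonthlyScheduleSummary(msw, msf, sdw, sdf, sdweek,
                                  int(w.sum()), int(f.sum()))


def social_jetlag_month(summary: MonthlyScheduleSummary) -> float:
    """Circular absolute difference between weekday and weekend mid-sleep, minutes."""
    return circular_diff_minutes(summary.midsleep_workdays, summary.midsleep_freedays)


def chronotype_month(summary: MonthlyScheduleSummary) -> float:
    """Sleep-debt-corrected mid-sleep on free days (MSFsc), clock minutes.

    MSFsc = MSF - (SDF - SDweek)/2 when free-day sleep exceeds workday sleep
    (the subject carries week-day sleep debt discharged on free days);
    otherwise MSF unchanged.  NaN when no free-day sleep exists.
    """
    msf = summary.midsleep_freedays
    if np.isnan(msf):
        return float("nan")
    sdf, sdw = summary.dur_freedays, summary.dur_workdays
    if not np.isnan(sdf) and not np.isnan(sdw) and sdf > sdw:
        return float((msf - (sdf - summary.dur_week) / 2.0) % MINUTES_PER_DAY)
    return float(msf)


# ---------------------------------------------------------------------------
# monthly aggregate block
# ---------------------------------------------------------------------------

_MEAN_FIELDS = ["timeInBed", "minutesAsleep", "minutesToFallAsleep",
                "minutesAfterWakeup", "deepMinutes", "remMinutes",
                "lightMinutes", "wakeMinutes"]


def monthly_sleep_aggregates(
    sessions: pd.DataFrame, grid: EpochGrid | None, month: int
) -> dict[str, float]:
    """The full monthly sleep feature block for one subject.

    Clock-valued outputs (startTime.sleep, chronotype) are raw clock minutes
    in [0, 1440); the feature pipeline re-encodes them as minutes from 18:00.
    Missing data yields NaN fields rather than errors.
    """
    if grid is None and len(sessions):
        grid = sessions_to_epochs(sessions)
    day, _, start_clock = (
        _session_day_and_clock(sessions) if len(sessions)
        else (pd.Series(dtype="datetime64[ns]"), np.array([]), np.array([]))
    )
    in_month = ((day >= month_start(month)) & (day < month_end(month))).to_numpy() \
        if len(sessions) else np.array([], dtype=bool)
    sess = sessions[in_month] if len(sessions) else sessions
    is_main = sess["isMainSleep"].to_numpy(bool) if len(sess) else np.array([], bool)
    main = sess[is_main] if len(sess) else sess
    naps = sess[~is_main] if len(sess) else sess

    out: dict[str, float] = {}
    day_in = day[in_month] if len(sessions) else day
    n_linked_days = int(day_in.nunique())
    out["log_count.sleep"] = float(n_linked_days) if n_linked_days else np.nan
    out["notMainSleep.counts"] = float(len(naps)) if n_linked_days else np.nan
    if n_linked_days:
        # mean over sleep-linked days of the day's total non-main asleep minutes
        nap_min = naps.groupby(day_in[~is_main])["minutesAsleep"].sum() \
            if len(naps) else pd.Series(dtype=float)
        out["notMainSleep.minutes"] = float(nap_min.sum()) / n_linked_days
    else:
        out["notMainSleep.minutes"] = np.nan
    for fld in _MEAN_FIELDS:
        out[fld] = float(main[fld].mean()) if len(main) else np.nan
    out["startTime.sleep"] = (
        circular_mean_clock(start_clock[in_month][is_main]) if len(main) else np.nan
    )
    summary = schedule_summary_month(sessions, month) if len(sessions) else \
        MonthlyScheduleSummary(np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0)
    out["SC_lag"] = social_jetlag_month(summary)
    out["chronotype"] = chronotype_month(summary)
    out["SRI"] = sri_month(grid, month) if grid is not None else np.nan
    return out


def _grouped_circular_mean(frame: pd.DataFrame, clock: np.ndarray, keys) -> pd.Series:
    """Circular mean of clock minutes per group; NaN on zero resultant."""
    ang = clock * (2 * np.pi / MINUTES_PER_DAY)
    tmp = pd.DataFrame({"cos": np.cos(ang), "sin": np.sin(ang)}, index=frame.index)
    for k in keys:
        tmp[k] = frame[k].to_numpy()
    s = tmp.groupby(keys)[["cos", "sin"]].sum()
    n = tmp.groupby(keys).size()
    r = np.hypot(s["cos"], s["sin"]) / n
    mean = (np.arctan2(s["sin"], s["cos"]) % (2 * np.pi)) * (MINUTES_PER_DAY / (2 * np.pi))
    mean[r < 1e-12] = np.nan
    return mean


def monthly_sleep_features(
    sleep_sessions: pd.DataFrame,
    study_start: int,
    study_end: int,
    clock_encoding: str = "minutes_from_18",
) -> pd.DataFrame:
    """Per-(subject, month) sleep feature table for a whole cohort.

    Vectorised with cohort-level groupbys (plus one epoch-grid pass per
    subject for SRI); agrees with :func:`monthly_sleep_aggregates` applied
    subject-month by subject-month.  ``clock_encoding='minutes_from_18'``
    re-encodes the two clock-valued features on a continuous scale;
    ``'clock'`` leaves raw minutes of day.
    """
    months = ym_range(study_start, study_end)
    df = sleep_sessions.reset_index(drop=True).copy()
    day, _, _ = _session_day_and_clock(df)
    df["_day"] = day
    df["_ym"] = day.dt.year * 100 + day.dt.month
    df = df[(df["_ym"] >= study_start) & (df["_ym"] <= study_end)].reset_index(drop=True)
    _, mid_clock, start_clock = _session_day_and_clock(df)
    keys = ["subject_id", "_ym"]

    full_index = pd.MultiIndex.from_product(
        [sorted(sleep_sessions["subject_id"].unique()), months],
        names=["subject_id", "ym"])
    out = pd.DataFrame(index=full_index, columns=SLEEP_FEATURES, dtype=float)

    is_main = df["isMainSleep"].to_numpy(bool)
    main = df[is_main]
    naps = df[~is_main]

    linked = df.groupby(keys)["_day"].nunique()
    out["log_count.sleep"] = linked.reindex(full_index).to_numpy()
    nap_counts = naps.groupby(keys).size()
    nap_minutes = naps.groupby(keys)["minutesAsleep"].sum()
    has_month = linked.reindex(full_index)
    out["notMainSleep.counts"] = nap_counts.reindex(full_index).fillna(0.0).where(
        has_month.notna()).to_numpy()
    out["notMainSleep.minutes"] = (
        nap_minutes.reindex(full_index).fillna(0.0) / has_month
    ).to_numpy()

    means = main.groupby(keys)[_MEAN_FIELDS].mean()
    for fld in _MEAN_FIELDS:
        out[fld] = means[fld].reindex(full_index).to_numpy()
    out["startTime.sleep"] = _grouped_circular_mean(
        main, start_clock[is_main], keys).reindex(full_index).to_numpy()

    # weekday/weekend schedule split for social jetlag + chronotype
    free = (main["_day"].dt.weekday >= 5).to_numpy()
    mw = _grouped_circular_mean(main[~free], mid_clock[is_main][~free], keys)
    mf = _grouped_circular_mean(main[free], mid_clock[is_main][free], keys)
    sdw = main[~free].groupby(keys)["minutesAsleep"].mean()
    sdf = main[free].groupby(keys)["minutesAsleep"].mean()
    mw = mw.reindex(full_index).to_numpy()
    mf = mf.reindex(full_index).to_numpy()
    sdw_v = sdw.reindex(full_index).to_numpy(float)
    sdf_v = sdf.reindex(full_index).to_numpy(float)

    d = np.abs(mw - mf) % MINUTES_PER_DAY
    out["SC_lag"] = np.minimum(d, MINUTES_PER_DAY - d)
    sdweek = np.where(np.isnan(sdw_v), sdf_v,
                      np.where(np.isnan(sdf_v), sdw_v,
                               (5.0 * sdw_v + 2.0 * sdf_v) / 7.0))
    with np.errstate(invalid="ignore"):
        debt = ~np.isnan(sdf_v) & ~np.isnan(sdw_v) & (sdf_v > sdw_v)
    chron = np.where(debt, (mf - (sdf_v - sdweek) / 2.0) % MINUTES_PER_DAY, mf)
    out["chronotype"] = chron

    # SRI: one grid pass per subject
    sri = {}
    for sid, sess in sleep_sessions.groupby("subject_id"):
        if len(sess) == 0:
            continue
        grid = sessions_to_epochs(sess)
        for ym in months:
            sri[(sid, ym)] = sri_month(grid, ym)
    out["SRI"] = [sri.get(key, np.nan) for key in full_index]

    if clock_encoding == "minutes_from_18":
        for key in ("startTime.sleep", "chronotype"):
            vals = out[key].to_numpy()
            out[key] = np.where(np.isnan(vals),
                                np.nan, (vals - 18 * 60) % MINUTES_PER_DAY)
    return out.reset_index()
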