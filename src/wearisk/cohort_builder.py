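"""Claims-based outcome labelling and observation-window construction.

The study outcome ("mental-illness onset") is the first month in which a
subject initiates BOTH a psychotropic prescription (ATC N05B hypnotics /
N05C anxiolytics / N06A antidepressants) and a psychiatric-visit procedure
code (I002 / I002-2).  Subjects whose two qualifying events first occur in
different months are excluded as discordant, as are subjects whose onset
falls before wearable linkage, in a gap of linkage, or within three months
of the first linked month.

Each retained subject contributes observation windows of three consecutive
calendar months, every month with at least ``min_linked_days`` device-linked
days; the binary label is onset in the month following the window.  A
subject with onset contributes exactly one window — the one ending the month
before onset; everyone else contributes every qualifying sliding window
whose following month is still observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._months import ym_add, ym_diff, ym_range
from .synthetic_cohort import RawCohort

__all__ = [
    "DRUG_KINDS",
    "VISIT_KINDS",
    "OnsetLabel",
    "ObservationWindow",
    "detect_onset",
    "detect_onsets",
    "compute_linkage",
    "apply_exclusions",
    "enumerate_windows",
    "build_windows",
]

logger = logging.getLogger(__name__)

DRUG_KINDS = frozenset({"drug_N05B", "drug_N05C", "drug_N06A"})
VISIT_KINDS = frozenset({"visit_I002", "visit_I002_2"})


@dataclass(frozen=True)
class OnsetLabel:
    subject_id: int
    status: str  # 'none' | 'onset' | 'excluded_discordant'
    onset_month: int | None = None  # yyyymm, present iff status == 'onset'

    def __post_init__(self) -> None:
        if (self.status == "onset") != (self.onset_month is not None):
            raise ValueError("onset_month must be set iff status == 'onset'")


@dataclass(frozen=True)
class ObservationWindow:
    subject_id: int
    m1: int
    m2: int
    m3: int
    exam_date: pd.Timestamp | None
    label: int

    def __post_init__(self) -> None:
        if ym_add(self.m1, 1) != self.m2 or ym_add(self.m2, 1) != self.m3:
            raise ValueError("window months must be consecutive")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def detect_onset(claims: pd.DataFrame, subject_id: int | None = None) -> OnsetLabel:
    """Label one subject from their claim events.

    Onset requires the first drug-class month and the first visit-code month
    to coincide; if both kinds occur but first in different months the subject
    is flagged ``excluded_discordant``.
    """
    if subject_id is None:
        if len(claims) == 0:
            raise ValueError("subject_id required for an empty claim set")
        ids = claims["subject_id"].unique()
        if len(ids) != 1:
            raise ValueError("claims must belong to a single subject")
        subject_id = int(ids[0])
    drug = claims.loc[claims["kind"].isin(DRUG_KINDS), "month"]
    visit = claims.loc[claims["kind"].isin(VISIT_KINDS), "month"]
    if drug.empty or visit.empty:
        return OnsetLabel(subject_id, "none")
    first_drug, first_visit = int(drug.min()), int(visit.min())
    if first_drug == first_visit:
        return OnsetLabel(subject_id, "onset", first_drug)
    return OnsetLabel(subject_id, "excluded_discordant")


def detect_onsets(claims: pd.DataFrame, subject_ids) -> dict[int, OnsetLabel]:
    """Vectorised :func:`detect_onset` over a whole claims table."""
    out: dict[int, OnsetLabel] = {int(s): OnsetLabel(int(s), "none") for s in subject_ids}
    if len(claims) == 0:
        return out
    drug = claims[claims["kind"].isin(DRUG_KINDS)].groupby("subject_id")["month"].min()
    visit = claims[claims["kind"].isin(VISIT_KINDS)].groupby("subject_id")["month"].min()
    both = drug.index.intersection(visit.index)
    for sid in both:
        sid = int(sid)
        if int(drug[sid]) == int(visit[sid]):
            out[sid] = OnsetLabel(sid, "onset", int(drug[sid]))
        else:
            out[sid] = OnsetLabel(sid, "excluded_discordant")
    return out


def compute_linkage(cohort: RawCohort) -> pd.DataFrame:
    """Per-(subject, month) linked-day counts.

    A day counts as linked if it has at least one sleep session OR one
    activity record; the two stream-specific day counts are kept separately
    (they feed the log_count.sleep / log_count.active features).
    Returns columns: subject_id, ym, sleep_days, active_days, linked_days.
    """
    sleep = cohort.sleep_sessions
    # day assignment: the calendar day containing the session midpoint
    mid = sleep["startTime"] + pd.to_timedelta(
        sleep["minutesToFallAsleep"]
        + (sleep["timeInBed"] - sleep["minutesToFallAsleep"]
           - sleep["minutesAfterWakeup"]) / 2.0, unit="m")
    sleep_days = pd.DataFrame({"subject_id": sleep["subject_id"],
                               "date": mid.dt.normalize()}).drop_duplicates()
    act_days = cohort.daily_activity[["subject_id", "date"]].drop_duplicates()

    union = pd.concat([sleep_days, act_days]).drop_duplicates()
    for frame in (sleep_days, act_days, union):
        frame["ym"] = frame["date"].dt.year * 100 + frame["date"].dt.month

    def _count(frame, name):
        return frame.groupby(["subject_id", "ym"]).size().rename(name)

    out = pd.concat(
        [_count(sleep_days, "sleep_days"), _count(act_days, "active_days"),
         _count(union, "linked_days")], axis=1
    ).fillna(0).astype(int).reset_index()
    return out


def apply_exclusions(
    subjects: pd.DataFrame,
    onsets: dict[int, OnsetLabel],
    linkage: pd.DataFrame,
) -> tuple[list[int], dict[str, int]]:
    """Drop subjects the study design cannot label cleanly.

    Exclusion reasons: discordant first-qualifying months; onset before the
    first linked month; onset in a month with no linked data (discontinued
    linking); onset within 3 months of the first linked month.
    Returns (kept subject ids, counts per exclusion reason).
    """
    report = {"discordant": 0, "onset_before_linkage": 0,
              "onset_during_gap": 0, "onset_within_3_months": 0}
    linked_months = linkage[linkage["linked_days"] > 0].groupby("subject_id")["ym"]
    first_linked = linked_months.min().to_dict()
    months_by_subject = (
        linkage[linkage["linked_days"] > 0].groupby("subject_id")["ym"].agg(set).to_dict()
    )
    kept: list[int] = []
    for sid in subjects["subject_id"]:
        sid = int(sid)
        label = onsets.get(sid, OnsetLabel(sid, "none"))
        if label.status == "excluded_discordant":
            report["discordant"] += 1
            continue
        if label.status == "onset":
            first = first_linked.get(sid)
            if first is None or label.onset_month < first:
                report["onset_before_linkage"] += 1
                continue
            if label.onset_month not in months_by_subject.get(sid, set()):
                report["onset_during_gap"] += 1
                continue
            if ym_diff(label.onset_month, first) < 3:
                report["onset_within_3_months"] += 1
                continue
        kept.append(sid)
    return kept, report


def _nearest_exam(exam_dates: np.ndarray, cutoff: pd.Timestamp,
                  lookback_months: int) -> pd.Timestamp | None:
    """Latest exam at or before *cutoff*, no older than the lookback horizon."""
    if len(exam_dates) == 0:
        return None
    eligible = exam_dates[exam_dates <= np.datetime64(cutoff)]
    if len(eligible) == 0:
        return None
    best = pd.Timestamp(eligible.max())
    if (cutoff - best).days > lookback_months * 31:
        return None
    return best


def enumerate_windows(
    linkage: "pd.Series | dict[int, int]",
    onset: OnsetLabel,
    exam_dates=None,
    min_linked_days: int = 15,
    study_start: int | None = None,
    study_end: int | None = None,
    sliding: bool = True,
    exam_lookback_months: int = 24,
) -> list[ObservationWindow]:
    """Windows for one subject given their per-month linked-day counts.

    *linkage* maps yyyymm -> linked-day count.  Negative subjects yield one
    label-0 window per qualifying 3-month run (sliding by default) whose
    following month is still inside the study period; an onset subject yields
    at most the single label-1 window ending the month before onset.
    """
    counts = dict(linkage.items() if hasattr(linkage, "items") else linkage)
    if not counts:
        return []
    if study_start is None:
        study_start = min(counts)
    if study_end is None:
        study_end = max(counts)
    exam_dates = (np.asarray(exam_dates, dtype="datetime64[ns]")
                  if exam_dates is not None else np.asarray([], dtype="datetime64[ns]"))

    months = ym_range(study_start, study_end)
    ok = [counts.get(m, 0) >= min_linked_days for m in months]

    def make(i3: int, label: int) -> ObservationWindow:
        m1, m2, m3 = months[i3 - 2], months[i3 - 1], months[i3]
        cutoff = pd.Timestamp(year=ym_add(m3, 1) // 100, month=ym_add(m3, 1) % 100,
                              day=1) - pd.Timedelta(days=1)
        exam = _nearest_exam(exam_dates, cutoff, exam_lookback_months)
        return ObservationWindow(onset.subject_id, m1, m2, m3, exam, label)

    if onset.status == "onset":
        target = ym_add(onset.onset_month, -1)
        if target not in months:
            return []
        i3 = months.index(target)
        if i3 >= 2 and ok[i3] and ok[i3 - 1] and ok[i3 - 2]:
            return [make(i3, 1)]
        logger.info("subject %s: onset %s has no eligible pre-onset window; dropped",
                    onset.subject_id, onset.onset_month)
        return []

    windows: list[ObservationWindow] = []
    i3 = 2
    # the following month (m3+1) must still be observed: m3 < study_end
    while i3 < len(months) - 1:
        if ok[i3] and ok[i3 - 1] and ok[i3 - 2]:
            windows.append(make(i3, 0))
            i3 += 1 if sliding else 3
        else:
            i3 += 1
    return windows


def build_windows(
    cohort: RawCohort,
    min_linked_days: int = 15,
    sliding: bool = True,
    exam_lookback_months: int = 24,
) -> tuple[pd.DataFrame, dict]:
    """Full labelling stage: onsets, exclusions, windows for a raw cohort.

    Returns (windows table, report).  The windows table has columns
    subject_id, m1, m2, m3, exam_date, label; the report carries exclusion
    counts and the number of onset subjects dropped for lack of an eligible
    pre-onset window.
    """
    onsets = detect_onsets(cohort.claims, cohort.subjects["subject_id"])
    linkage = compute_linkage(cohort)
    kept, report = apply_exclusions(cohort.subjects, onsets, linkage)

    link_by_subject = {
        int(sid): dict(zip(grp["ym"], grp["linked_days"]))
        for sid, grp in linkage.groupby("subject_id")
    }
    exams_by_subject = {
        int(sid): grp["exam_date"].values
        for sid, grp in cohort.exams.groupby("subject_id")
    }
    study_start = cohort.study_start or int(linkage["ym"].min())
    study_end = cohort.study_end or int(linkage["ym"].max())

    rows = []
    dropped_positives = 0
    for sid in kept:
        onset = onsets[sid]
        wins = enumerate_windows(
            link_by_subject.get(sid, {}), onset,
            exam_dates=exams_by_subject.get(sid),
            min_linked_days=min_linked_days, study_start=study_start,
            study_end=study_end, sliding=sliding,
            exam_lookback_months=exam_lookback_months,
        )
        if onset.status == "onset" and not wins:
            dropped_positives += 1
        rows.extend(
            (w.subject_id, w.m1, w.m2, w.m3, w.exam_date, w.label) for w in wins
        )
    windows = pd.DataFrame(rows, columns=["subject_id", "m1", "m2", "m3",
                                          "exam_date", "label"])
    report = {**report, "positive_without_window": dropped_positives,
              "n_windows": len(windows),
              "n_positive_windows": int(windows["label"].sum()) if len(windows) else 0,
              "n_subjects": len(kept)}
    return windows, report
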