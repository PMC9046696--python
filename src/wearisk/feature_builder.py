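"""Assemble the model feature matrix.

One row per observation window: three monthly wearable blocks with ``1``-``3``
suffixes (suffix 1 = earliest month of the window), the medical-exam block
copied from the window's attached exam, demographics and calendar fields, and
the binary onset label.  Missing values stay missing (NaN) — the boosted-tree
learner routes them natively, and keeping them preserves the differing
per-feature record counts real extractions show.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .sleep_metrics import SLEEP_FEATURES
from .synthetic_cohort import EXAM_VALUE_COLUMNS

__all__ = [
    "ACTIVITY_FEATURES",
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "monthly_activity_aggregates",
    "activity_feature_table",
    "build_feature_table",
    "feature_matrix",
    "write_schema",
    "leakage_audit",
]

ACTIVITY_FEATURES = [
    "RHR", "veryActiveMinutes", "fairlyActiveMinutes", "lightlyActiveMinutes",
    "Steps", "log_count.active",
]

MONTHLY_FEATURES = ACTIVITY_FEATURES + SLEEP_FEATURES

#: fixed, versioned model-feature schema (order matters)
FEATURE_COLUMNS = (
    [f"{name}{n}" for n in (1, 2, 3) for name in MONTHLY_FEATURES]
    + EXAM_VALUE_COLUMNS
    + ["GENDER", "AGE", "YM", "YEAR", "MONTH"]
)

META_COLUMNS = ["subject_id", "m1", "m2", "m3", "exam_date", "label"]


def activity_feature_table(
    daily_activity: pd.DataFrame, daily_rhr: pd.DataFrame
) -> pd.DataFrame:
    """Per-(subject, month) activity/heart-rate block: monthly means over
    linked days plus the count of activity-linked days."""
    act = daily_activity.copy()
    act["ym"] = act["date"].dt.year * 100 + act["date"].dt.month
    g = act.groupby(["subject_id", "ym"])
    out = g[["veryActiveMinutes", "fairlyActiveMinutes", "lightlyActiveMinutes"]].mean()
    out["Steps"] = g["steps"].mean()
    out["log_count.active"] = g["date"].nunique().astype(float)

    rhr = daily_rhr.copy()
    if len(rhr):
        rhr["ym"] = rhr["date"].dt.year * 100 + rhr["date"].dt.month
        out["RHR"] = rhr.groupby(["subject_id", "ym"])["RestingHeartRate"].mean()
    else:
        out["RHR"] = np.nan
    return out[ACTIVITY_FEATURES].reset_index()


def monthly_activity_aggregates(
    daily_activity: pd.DataFrame, daily_rhr: pd.DataFrame, month: int
) -> dict[str, float]:
    """Single subject-month activity block (thin wrapper over the table form)."""
    table = activity_feature_table(daily_activity, daily_rhr)
    row = table[table["ym"] == month]
    if len(row) == 0:
        return {name: float("nan") for name in ACTIVITY_FEATURES}
    if len(row) > 1:
        raise ValueError("monthly_activity_aggregates expects a single subject")
    return {name: float(row.iloc[0][name]) for name in ACTIVITY_FEATURES}


def build_feature_table(
    windows: pd.DataFrame,
    sleep_monthly: pd.DataFrame,
    activity_monthly: pd.DataFrame,
    exams: pd.DataFrame,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """One feature row per window; columns META_COLUMNS + FEATURE_COLUMNS.

    Monthly blocks join on (subject_id, window month n); the exam block joins
    on the window's attached exam_date (all-missing when absent); AGE is the
    age at the end of the third window month.
    """
    known = set(subjects["subject_id"])
    missing_ref = set(windows["subject_id"]) - known
    if missing_ref:
        raise ValueError(f"windows reference unknown subjects: {sorted(missing_ref)[:5]}")

    out = windows[["subject_id", "m1", "m2", "m3", "exam_date", "label"]].copy()
    monthly = sleep_monthly.merge(activity_monthly, on=["subject_id", "ym"], how="outer")
    for n, mcol in ((1, "m1"), (2, "m2"), (3, "m3")):
        block = monthly.rename(
            columns={name: f"{name}{n}" for name in MONTHLY_FEATURES})
        out = out.merge(block, left_on=["subject_id", mcol],
                        right_on=["subject_id", "ym"], how="left")
        out = out.drop(columns=["ym"])

    exam_block = exams[["subject_id", "exam_date"] + EXAM_VALUE_COLUMNS] \
        .drop_duplicates(["subject_id", "exam_date"])
    out = out.merge(exam_block, on=["subject_id", "exam_date"], how="left")

    out = out.merge(subjects[["subject_id", "GENDER", "birth_year"]],
                    on="subject_id", how="left")
    out["YM"] = out["m3"]
    out["YEAR"] = out["m3"] // 100
    out["MONTH"] = out["m3"] % 100
    out["AGE"] = (out["YEAR"] - out["birth_year"]).astype(float)
    out = out.drop(columns=["birth_year"])
    return out[META_COLUMNS + FEATURE_COLUMNS]


def feature_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Split a feature table into (X, y, subject_ids) for the learner."""
    X = features[FEATURE_COLUMNS].astype(float)
    y = features["label"].to_numpy(int)
    groups = features["subject_id"].to_numpy()
    return X, y, groups


def write_schema(path: str) -> None:
    """Dump the fixed feature schema (name, block, dtype) as JSON."""
    def block_of(col: str) -> str:
        if col in EXAM_VALUE_COLUMNS:
            return "exam"
        if col in ("GENDER", "AGE", "YM", "YEAR", "MONTH"):
            return "demographics/calendar"
        return f"wearable month {col[-1]}"

    schema = [{"name": c, "block": block_of(c), "dtype": "float",
               "missing": "NaN"} for c in FEATURE_COLUMNS]
    with open(path, "w") as fh:
        json.dump({"version": 1, "columns": schema}, fh, indent=1)


def leakage_audit(features: pd.DataFrame) -> pd.DataFrame:
    """Rows whose exam date postdates the end of window month 3 (should be none)."""
    end_m3 = pd.to_datetime((features["m3"] // 100).astype(str)
                            + "-" + (features["m3"] % 100).astype(str).str.zfill(2)) \
        + pd.offsets.MonthEnd(1)
    exam = pd.to_datetime(features["exam_date"])
    return features[exam.notna() & (exam > end_m3)]
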