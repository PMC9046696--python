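"""End-to-end convenience wrappers: raw cohort -> features -> CV -> report."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cohort_builder, feature_builder, risk_model, sleep_metrics
from .risk_model import CVResult, ModelConfig
from .synthetic_cohort import GeneratorConfig, RawCohort, generate_cohort


def build_features(
    cohort: RawCohort, min_linked_days: int = 15, sliding: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Windows + monthly blocks + exams + demographics -> feature table."""
    windows, report = cohort_builder.build_windows(
        cohort, min_linked_days=min_linked_days, sliding=sliding)
    sleep_monthly = sleep_metrics.monthly_sleep_features(
        cohort.sleep_sessions, cohort.study_start, cohort.study_end)
    activity_monthly = feature_builder.activity_feature_table(
        cohort.daily_activity, cohort.daily_rhr)
    features = feature_builder.build_feature_table(
        windows, sleep_monthly, activity_monthly, cohort.exams, cohort.subjects)
    return features, report


@dataclass
class PipelineResult:
    features: pd.DataFrame
    window_report: dict
    cv: CVResult


def run_pipeline(
    gen_config: GeneratorConfig, model_config: ModelConfig | None = None
) -> PipelineResult:
    """Generate a synthetic cohort and evaluate the risk model on it."""
    cohort = generate_cohort(gen_config)
    features, report = build_features(cohort)
    X, y, groups = feature_builder.feature_matrix(features)
    config = model_config or ModelConfig(seed=gen_config.seed)
    cv = risk_model.repeated_group_cv(X, y, groups, config)
    return PipelineResult(features, report, cv)
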