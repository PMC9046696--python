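"""Split-threshold interpretability for the fitted boosted-tree ensemble.

Boosted trees with interactions do not admit a single per-feature effect
direction, so the model is read directly from its tree dump: for each
high-importance feature, collect every branch threshold used anywhere in the
ensemble, take the most frequent one (the *mode split*) and the fraction of
that feature's branches using it (*cover*), then split the training windows
at the mode value and compare onset rates below vs at-or-above with a
two-sided Fisher exact test.  Branches can also be read conditionally on
their parent-path conditions, reproducing how a split behaves only for the
records that actually reach it.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .risk_model import GroupComparison, fisher_exact_two_sided

__all__ = [
    "SplitRecord",
    "ModeSplitResult",
    "parse_model_dump",
    "gain_importance",
    "mode_split",
    "group_by_feature_threshold",
    "conditional_path_split",
    "paths_for_feature",
    "interpretability_report",
]


@dataclass(frozen=True)
class SplitRecord:
    """One internal node of one tree."""

    tree: int
    node: int
    feature: str
    threshold: float
    gain: float
    #: root-to-parent conditions as (feature, 'lt'|'ge', threshold)
    path: tuple[tuple[str, str, float], ...] = ()


@dataclass
class ModeSplitResult:
    feature: str
    mode_value: float
    cover: float
    n_mode: int
    n_splits: int
    comparison: GroupComparison


def _walk(node: dict, tree_idx: int, path: tuple, out: list[SplitRecord]) -> None:
    if "leaf" in node:
        return
    for key in ("split", "split_condition", "children"):
        if key not in node:
            raise ValueError(f"malformed dump at tree {tree_idx}: missing {key!r}")
    feat = node["split"]
    thr = float(node["split_condition"])
    out.append(SplitRecord(tree_idx, int(node["nodeid"]), feat, thr,
                           float(node.get("gain", 0.0)), path))
    yes_id, no_id = node.get("yes"), node.get("no")
    for child in node["children"]:
        cid = child.get("nodeid")
        direction = "lt" if cid == yes_id else "ge"
        _walk(child, tree_idx, path + ((feat, direction, thr),), out)


def parse_model_dump(model) -> list[SplitRecord]:
    """Flatten an ensemble into split records (internal nodes only).

    *model* may be a fitted ``xgb.Booster`` or an iterable of per-tree JSON
    strings as produced by ``Booster.get_dump(dump_format='json',
    with_stats=True)``.
    """
    if isinstance(model, xgb.Booster):
        dump = model.get_dump(dump_format="json", with_stats=True)
    else:
        dump = list(model)
    records: list[SplitRecord] = []
    for i, tree_json in enumerate(dump):
        try:
            tree = json.loads(tree_json) if isinstance(tree_json, str) else tree_json
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed dump at tree {i}: {exc}") from exc
        _walk(tree, i, (), records)
    return records


def gain_importance(records: list[SplitRecord]) -> pd.DataFrame:
    """Per-feature total gain, normalised to fractions, sorted descending."""
    if not records:
        raise ValueError("empty ensemble: no split records")
    totals: Counter = Counter()
    for rec in records:
        totals[rec.feature] += rec.gain
    table = pd.DataFrame(
        sorted(totals.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "total_gain"],
    )
    table["fraction"] = table["total_gain"] / table["total_gain"].sum()
    return table


def mode_split(
    records: list[SplitRecord], feature: str, precision: int | None = None
) -> tuple[float, float, int, int]:
    """Most frequent split threshold for *feature* and its cover.

    Returns (mode value, cover, multiplicity, total splits on feature).
    Thresholds compare by exact dump value unless ``precision`` rounds them
    first; a tie between threshold values resolves to the smallest.
    """
    thresholds = [rec.threshold if precision is None else round(rec.threshold, precision)
                  for rec in records if rec.feature == feature]
    if not thresholds:
        raise ValueError(f"feature {feature!r} is never used in a split")
    counts = Counter(thresholds)
    top = max(counts.values())
    mode = min(v for v, k in counts.items() if k == top)
    return float(mode), top / len(thresholds), top, len(thresholds)


def _apply_condition(x: pd.Series, op: str, threshold: float) -> pd.Series:
    if op in ("lt", "<"):
        return x < threshold
    if op in ("ge", ">="):
        return x >= threshold
    raise ValueError(f"unknown condition operator {op!r}")


def group_by_feature_threshold(
    features: pd.DataFrame, labels, feature: str, threshold: float
) -> GroupComparison:
    """Onset-rate comparison of rows below vs at-or-above *threshold*.

    Rows with the feature missing are excluded and counted in ``n_missing``.
    """
    if feature not in features.columns:
        raise ValueError(f"feature {feature!r} not in schema")
    x = features[feature]
    y = np.asarray(labels)
    present = x.notna().to_numpy()
    if not present.any():
        raise ValueError(f"feature {feature!r} is missing for every row")
    xp = x.to_numpy(float)[present]
    yp = y[present]
    high = xp >= threshold
    n_high, x_high = int(high.sum()), int(yp[high].sum())
    n_low, x_low = int((~high).sum()), int(yp[~high].sum())
    degenerate = n_high == 0 or n_low == 0
    pval = float("nan") if degenerate else fisher_exact_two_sided(
        x_low, n_low - x_low, x_high, n_high - x_high)
    return GroupComparison(n_low, x_low, n_high, x_high, pval, degenerate,
                           n_missing=int((~present).sum()))


def conditional_path_split(
    features: pd.DataFrame, labels, conditions, feature: str, threshold: float
) -> GroupComparison:
    """Apply *conditions* (as on a tree path), then split at the threshold.

    *conditions* is an iterable of (feature, op, threshold) with op in
    {'lt', 'ge'} (aliases '<', '>='); rows failing or missing any condition
    are dropped before grouping.
    """
    mask = pd.Series(True, index=features.index)
    for feat, op, thr in conditions:
        if feat not in features.columns:
            raise ValueError(f"condition feature {feat!r} not in schema")
        mask &= _apply_condition(features[feat], op, thr).fillna(False)
    if not mask.any():
        return GroupComparison(0, 0, 0, 0, float("nan"), degenerate=True)
    return group_by_feature_threshold(
        features[mask], np.asarray(labels)[mask.to_numpy()], feature, threshold)


def paths_for_feature(
    records: list[SplitRecord], feature: str, threshold: float | None = None
) -> list[tuple[tuple[str, str, float], ...]]:
    """Parent-condition paths of every branch splitting on *feature*
    (optionally only branches at one threshold value)."""
    return [rec.path for rec in records
            if rec.feature == feature
            and (threshold is None or rec.threshold == threshold)]


def interpretability_report(
    model, features: pd.DataFrame, labels, top_k: int = 10,
    precision: int | None = None,
) -> list[ModeSplitResult]:
    """Mode-split table for the *top_k* features by gain importance."""
    records = parse_model_dump(model)
    ranking = gain_importance(records)
    out: list[ModeSplitResult] = []
    for feature in ranking["feature"].head(top_k):
        value, cover, k, n = mode_split(records, feature, precision=precision)
        comp = group_by_feature_threshold(features, labels, feature, value)
        out.append(ModeSplitResult(feature, value, cover, k, n, comp))
    return out
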