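"""Imbalanced boosted-tree risk model with repeated stratified group CV.

The classifier is an XGBoost binary-logistic ensemble trained with a weighted
logloss: positive windows (onset in the following month) carry weight
``class_weight``, negatives weight 1, which for this loss is realised exactly
by per-instance weights.  Evaluation is repeated stratified group k-fold
cross-validation: all windows of a subject stay in one fold, positive
subjects are spread as evenly as possible over folds, the out-of-fold
predictions of a repeat are pooled and a single merged AUC computed, and the
mean/SD across repeats reported.

Also provides the downstream statistics: ROC with the closest-to-(0,1)
operating point, per-class probability density curves, probability-threshold
risk grouping, and a two-sided Fisher exact test (exact big-integer
hypergeometric enumeration).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import gammaln
from scipy.stats import gaussian_kde, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ModelConfig",
    "CVResult",
    "GroupComparison",
    "RocResult",
    "make_group_stratified_folds",
    "instance_weights",
    "weighted_logloss",
    "fit_boosted_model",
    "repeated_group_cv",
    "merged_auc",
    "roc_curve_and_cutoff",
    "probability_density_curves",
    "threshold_grouping",
    "fisher_exact_two_sided",
    "grid_search",
]

_PROB_EPS = 1e-15


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the selected values of the reference fit."""

    eta: float = 0.05
    max_depth: int = 2
    min_child_weight: float = 16.0
    colsample_bytree: float = 0.8
    class_weight: float = 10.0
    nrounds: int = 137
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    nthread: int = 1
    #: grid-search space over the four tuned hyperparameters
    grid: dict[str, list] = field(default_factory=dict)

    def validate(self) -> None:
        if self.class_weight < 1:
            raise ValueError("class_weight must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.nrounds < 1:
            raise ValueError("nrounds must be >= 1")

    def xgb_params(self) -> dict:
        return {
            "objective": "binary:logistic",
            "base_score": 0.5,
            "eta": self.eta,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "colsample_bytree": self.colsample_bytree,
            "tree_method": "hist",
            "nthread": self.nthread,
            "seed": self.seed,
        }


@dataclass
class CVResult:
    """Pooled out-of-fold probabilities and per-repeat merged AUCs."""

    oof: np.ndarray            # shape (n_repeats, n_windows)
    aucs: list[float]          # merged AUC per repeat
    fold_maps: list[dict]      # subject -> fold, per repeat
    config: ModelConfig

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass
class GroupComparison:
    """2x2 onset-by-group comparison with a two-sided Fisher exact p."""

    n_low: int
    x_low: int
    n_high: int
    x_high: int
    p_value: float
    degenerate: bool = False
    n_missing: int = 0

    @property
    def prop_low(self) -> float:
        return self.x_low / self.n_low if self.n_low else float("nan")

    @property
    def prop_high(self) -> float:
        return self.x_high / self.n_high if self.n_high else float("nan")


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def make_group_stratified_folds(
    windows: pd.DataFrame, n_folds: int, seed: int
) -> dict[int, int]:
    """Deterministic subject -> fold map.

    All windows of a subject share a fold; positive subjects (any label-1
    window) are spread as evenly as possible.  Subjects are shuffled by
    *seed*, stably sorted into (positive, negative) strata ordered by window
    count, and snake-assigned across folds so window counts stay balanced.
    """
    per_subject = windows.groupby("subject_id")["label"].agg(["max", "size"])
    if len(per_subject) < n_folds:
        raise ValueError(
            f"need at least {n_folds} subjects for {n_folds} folds, "
            f"got {len(per_subject)}")
    rng = np.random.default_rng(seed)
    subjects = per_subject.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1)))
    subjects = subjects.sort_values(["max", "size"], ascending=[False, False],
                                    kind="stable")
    assignment: dict[int, int] = {}
    for rank, sid in enumerate(subjects.index):
        cycle, pos = divmod(rank, n_folds)
        fold = pos if cycle % 2 == 0 else n_folds - 1 - pos
        assignment[int(sid)] = fold
    return assignment


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def instance_weights(labels: np.ndarray, class_weight: float) -> np.ndarray:
    """class_weight for positives, 1 for negatives."""
    y = np.asarray(labels)
    return np.where(y == 1, float(class_weight), 1.0)


def weighted_logloss(labels, probs, class_weight: float = 1.0) -> float:
    """Weight-normalised cross-entropy; probabilities clipped into (0,1)."""
    y = np.asarray(labels, float)
    p = np.asarray(probs, float)
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn(
            f"probabilities outside (0,1) clipped at eps={_PROB_EPS}",
            RuntimeWarning, stacklevel=2)
        p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
    w = instance_weights(y, class_weight)
    ll = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(np.sum(w * ll) / np.sum(w))


# ---------------------------------------------------------------------------
# model fit and cross-validation
# ---------------------------------------------------------------------------

def fit_boosted_model(
    X: pd.DataFrame, y: np.ndarray, config: ModelConfig,
    nrounds: int | None = None,
) -> xgb.Booster:
    """Train the weighted boosted-tree ensemble on the full input."""
    config.validate()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    dtrain = xgb.DMatrix(X, label=y,
                         weight=instance_weights(y, config.class_weight),
                         missing=np.nan)
    return xgb.train(config.xgb_params(), dtrain,
                     num_boost_round=nrounds or config.nrounds)


def repeated_group_cv(
    X: pd.DataFrame, y: np.ndarray, groups: np.ndarray, config: ModelConfig
) -> CVResult:
    """Repeated stratified group k-fold CV with merged-fold AUC per repeat.

    Each repeat re-cuts the folds with seed ``config.seed + repeat``; every
    window is scored exactly once per repeat by the model trained without its
    subject.
    """
    config.validate()
    y = np.asarray(y)
    groups = np.asarray(groups)
    windows = pd.DataFrame({"subject_id": groups, "label": y})
    oof = np.full((config.n_repeats, len(y)), np.nan)
    aucs: list[float] = []
    fold_maps: list[dict] = []
    params = config.xgb_params()
    for rep in range(config.n_repeats):
        fold_of = make_group_stratified_folds(windows, config.n_folds,
                                              config.seed + rep)
        folds = np.asarray([fold_of[int(s)] for s in groups])
        for k in range(config.n_folds):
            val = folds == k
            tr = ~val
            dtrain = xgb.DMatrix(X[tr], label=y[tr],
                                 weight=instance_weights(y[tr], config.class_weight),
                                 missing=np.nan)
            booster = xgb.train(params, dtrain, num_boost_round=config.nrounds)
            oof[rep, val] = booster.predict(xgb.DMatrix(X[val], missing=np.nan))
        aucs.append(merged_auc(oof[rep], y))
        fold_maps.append(fold_of)
    return CVResult(oof=oof, aucs=aucs, fold_maps=fold_maps, config=config)


def select_nrounds(
    X: pd.DataFrame, y: np.ndarray, groups: np.ndarray, config: ModelConfig,
    max_rounds: int = 500, patience: int = 20,
) -> int:
    """Boosting-round count by early stopping on one group-held-out fold.

    The first stratified group fold serves as the validation set; training
    stops when its weighted logloss has not improved for *patience* rounds.
    """
    windows = pd.DataFrame({"subject_id": groups, "label": y})
    fold_of = make_group_stratified_folds(windows, config.n_folds, config.seed)
    folds = np.asarray([fold_of[int(s)] for s in groups])
    val = folds == 0
    dtrain = xgb.DMatrix(X[~val], label=y[~val],
                         weight=instance_weights(y[~val], config.class_weight),
                         missing=np.nan)
    dval = xgb.DMatrix(X[val], label=y[val],
                       weight=instance_weights(y[val], config.class_weight),
                       missing=np.nan)
    booster = xgb.train(config.xgb_params(), dtrain, num_boost_round=max_rounds,
                        evals=[(dval, "val")], early_stopping_rounds=patience,
                        verbose_eval=False)
    return int(booster.best_iteration) + 1


def merged_auc(probs, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction."""
    y = np.asarray(labels)
    p = np.asarray(probs, float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# downstream statistics
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    best_index: int

    @property
    def best_point(self) -> tuple[float, float]:
        return float(self.fpr[self.best_index]), float(self.tpr[self.best_index])

    @property
    def cutoff(self) -> float:
        return float(self.thresholds[self.best_index])


def roc_curve_and_cutoff(probs, labels) -> RocResult:
    """Full ROC plus the operating point closest (Euclidean) to (0, 1)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined with a single class")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(probs, float))
    dist2 = fpr**2 + (1.0 - tpr) ** 2
    best = int(np.argmin(dist2))
    return RocResult(fpr, tpr, thr, best)


def probability_density_curves(
    probs, labels, bw_method="scott", grid_size: int = 512,
    support: tuple[float, float] = (0.0, 1.0),
):
    """Per-class Gaussian KDE of the predicted onset probability.

    Boundary mass is reflected at both support edges so each curve integrates
    to ~1 on its evaluation grid even when predictions pile up near 0.
    Returns (grid, density_class0, density_class1).
    """
    y = np.asarray(labels)
    p = np.asarray(probs, float)
    lo, hi = support
    xs = np.linspace(lo, hi, grid_size)

    def one_class(values: np.ndarray) -> np.ndarray:
        if len(values) < 2:
            raise ValueError("need >= 2 points per class for a density curve")
        if np.std(values) < 1e-12:
            # degenerate point mass: narrow Gaussian bump, reflected
            sigma = max((hi - lo) * 1e-3, 1e-9)
            mu = values[0]
            dens = np.zeros_like(xs)
            for m in (mu, 2 * lo - mu, 2 * hi - mu):
                dens += np.exp(-0.5 * ((xs - m) / sigma) ** 2) / (
                    sigma * np.sqrt(2 * np.pi))
            return dens
        kde = gaussian_kde(values, bw_method=bw_method)
        return kde(xs) + kde(2 * lo - xs) + kde(2 * hi - xs)

    return xs, one_class(p[y == 0]), one_class(p[y == 1])


def threshold_grouping(probs, labels, threshold: float) -> GroupComparison:
    """Split windows at a predicted-probability threshold and Fisher-test the
    onset rates.  The high-risk group is ``prob >= threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(labels)
    p = np.asarray(probs, float)
    high = p >= threshold
    n_high, x_high = int(high.sum()), int(y[high].sum())
    n_low, x_low = int((~high).sum()), int(y[~high].sum())
    degenerate = n_high == 0 or n_low == 0
    pval = float("nan") if degenerate else fisher_exact_two_sided(
        x_low, n_low - x_low, x_high, n_high - x_high)
    return GroupComparison(n_low, x_low, n_high, x_high, pval, degenerate)


def _fisher_exact_logspace(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p via log-gamma pmf (for very wide table supports)."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def logpmf(k: int) -> float:
        return (gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
                + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
                - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = logpmf(a)
    lps = np.array([logpmf(k) for k in range(lo, hi + 1)])
    keep = lps <= lp_obs + np.log1p(1e-7)
    m = lps[keep].max()
    return float(min(1.0, np.exp(m) * np.exp(lps[keep] - m).sum()))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (relative
    tolerance 1 + 1e-7, the standard convention).  Exact big-integer
    arithmetic when the table support is modest, log-gamma otherwise.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if hi - lo > 4096:
        return _fisher_exact_logspace(a, b, c, d)
    num_obs = math.comb(r1, a) * math.comb(r2, c)
    scale = 10**7
    total = 0
    for k in range(lo, hi + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num_k * scale <= num_obs * (scale + 1):
            total += num_k
    p = Fraction(total, math.comb(n, c1))
    return min(1.0, float(p))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

DEFAULT_GRID = {
    "max_depth": [2, 3, 4],
    "min_child_weight": [1.0, 4.0, 16.0],
    "colsample_bytree": [0.8, 1.0],
    "class_weight": [1.0, 10.0, 20.0],
}


def grid_search(
    X: pd.DataFrame, y: np.ndarray, groups: np.ndarray,
    config: ModelConfig, grid: dict[str, list] | None = None,
    n_repeats: int = 2,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Pick the hyperparameter combination with the best mean merged-fold AUC.

    Ties break toward the simpler model: smaller max_depth, then larger
    min_child_weight.
    """
    grid = grid or config.grid or DEFAULT_GRID
    names = sorted(grid)
    records = []
    for combo in product(*(grid[k] for k in names)):
        cand = replace(config, n_repeats=n_repeats, **dict(zip(names, combo)))
        result = repeated_group_cv(X, y, groups, cand)
        records.append({**dict(zip(names, combo)), "mean_auc": result.mean_auc,
                        "sd_auc": result.sd_auc})
    sort_cols = [c for c in ("mean_auc", "max_depth", "min_child_weight")
                 if c == "mean_auc" or c in names]
    table = pd.DataFrame(records).sort_values(
        sort_cols, ascending=[c != "mean_auc" and c != "min_child_weight"
                              for c in sort_cols],
        kind="stable").reset_index(drop=True)
    best = replace(config, **{k: table.iloc[0][k] for k in names})
    best.max_depth = int(best.max_depth)
    return best, table
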