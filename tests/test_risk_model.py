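import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from sklearn.metrics import roc_auc_score

from wearisk.risk_model import (
    ModelConfig,
    fisher_exact_two_sided,
    fit_boosted_model,
    instance_weights,
    make_group_stratified_folds,
    merged_auc,
    probability_density_curves,
    repeated_group_cv,
    roc_curve_and_cutoff,
    threshold_grouping,
    weighted_logloss,
)


def windows_frame(n_subjects, pos_subjects, windows_per_subject=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(n_subjects):
        k = windows_per_subject + int(rng.integers(0, 3))
        label = 1 if sid < pos_subjects else 0
        for _ in range(k):
            rows.append((sid, label))
    return pd.DataFrame(rows, columns=["subject_id", "label"])


class TestFolds:
    def test_all_windows_of_a_subject_share_a_fold(self):
        windows = windows_frame(40, 5)
        fold_of = make_group_stratified_folds(windows, 5, seed=1)
        folds = windows["subject_id"].map(fold_of)
        assert folds.groupby(windows["subject_id"]).nunique().eq(1).all()
        assert set(folds) == set(range(5))

    def test_positive_subjects_spread_by_pigeonhole(self):
        windows = windows_frame(200, 24)
        fold_of = make_group_stratified_folds(windows, 10, seed=3)
        pos_subjects = windows.loc[windows["label"] == 1, "subject_id"].unique()
        per_fold = pd.Series([fold_of[s] for s in pos_subjects]).value_counts()
        assert set(per_fold) <= {2, 3}

    def test_deterministic_given_seed(self):
        windows = windows_frame(50, 6)
        a = make_group_stratified_folds(windows, 5, seed=9)
        b = make_group_stratified_folds(windows, 5, seed=9)
        c = make_group_stratified_folds(windows, 5, seed=10)
        assert a == b
        assert a != c

    def test_more_folds_than_subjects_errors(self):
        windows = windows_frame(4, 1)
        with pytest.raises(ValueError, match="subjects"):
            make_group_stratified_folds(windows, 10, seed=0)


class TestWeightedLogloss:
    def test_perfect_predictions_near_zero(self):
        y = np.array([0, 1, 0, 1])
        p = np.array([1e-12, 1 - 1e-12, 1e-12, 1 - 1e-12])
        assert weighted_logloss(y, p, class_weight=10) < 1e-10

    def test_single_positive_at_half_is_ln2(self):
        assert weighted_logloss([1], [0.5], class_weight=10) == pytest.approx(
            np.log(2))

    def test_class_weight_one_is_unweighted(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        unweighted = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert weighted_logloss(y, p, 1.0) == pytest.approx(unweighted)

    def test_weight_vector(self):
        w = instance_weights(np.array([0, 1, 1, 0]), 10)
        assert list(w) == [1.0, 10.0, 10.0, 1.0]

    def test_out_of_range_probs_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            val = weighted_logloss([1, 0], [1.0, 0.0], 1.0)
        assert np.isfinite(val)


class TestMergedAUC:
    def test_perfect_separation(self):
        assert merged_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pair_counting_example(self):
        # pos {0.8, 0.3}, neg {0.5, 0.1}: 3 of 4 pairs ordered correctly
        assert merged_auc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert merged_auc([0.5] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            merged_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[:2] = [0, 1]
        p = np.round(rng.random(n), 1)  # coarse grid forces ties
        pos, neg = p[y == 1], p[y == 0]
        wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
        assert merged_auc(p, y) == pytest.approx(wins / (len(pos) * len(neg)))
        assert merged_auc(p, y) == pytest.approx(roc_auc_score(y, p))


class TestRocCutoff:
    def test_perfect_scores_hit_top_left(self):
        roc = roc_curve_and_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.best_point == (0.0, 1.0)

    def test_exhaustive_threshold_oracle(self):
        p = np.array([0.1, 0.3, 0.35, 0.4, 0.8, 0.9])
        y = np.array([0, 0, 1, 0, 1, 1])
        roc = roc_curve_and_cutoff(p, y)
        best = None
        for thr in np.unique(np.concatenate([[0.0], p, [1.0]])):
            high = p >= thr
            tpr = (y[high] == 1).sum() / (y == 1).sum()
            fpr = (y[high] == 0).sum() / (y == 0).sum()
            d = fpr**2 + (1 - tpr) ** 2
            if best is None or d < best[0]:
                best = (d, fpr, tpr)
        assert roc.best_point == pytest.approx((best[1], best[2]))

    def test_monotone_curve(self):
        rng = np.random.default_rng(4)
        p = rng.random(100)
        y = rng.integers(0, 2, 100)
        roc = roc_curve_and_cutoff(p, y)
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()


class TestDensities:
    def test_point_mass_peaks_at_value(self):
        xs, d0, d1 = probability_density_curves([0.2, 0.2, 0.7, 0.7], [0, 0, 1, 1])
        assert xs[np.argmax(d0)] == pytest.approx(0.2, abs=0.01)
        assert xs[np.argmax(d1)] == pytest.approx(0.7, abs=0.01)

    def test_each_curve_integrates_to_one(self):
        rng = np.random.default_rng(6)
        p = np.clip(rng.beta(1, 30, 500), 1e-4, 1)  # piled up near 0
        y = rng.integers(0, 2, 500)
        xs, d0, d1 = probability_density_curves(p, y)
        assert np.trapezoid(d0, xs) == pytest.approx(1.0, abs=0.01)
        assert np.trapezoid(d1, xs) == pytest.approx(1.0, abs=0.01)

    def test_separated_classes_have_ordered_modes(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.normal(0.2, 0.03, 200), rng.normal(0.6, 0.03, 50)])
        y = np.array([0] * 200 + [1] * 50)
        xs, d0, d1 = probability_density_curves(np.clip(p, 0, 1), y)
        assert xs[np.argmax(d0)] < xs[np.argmax(d1)]

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            probability_density_curves([0.5, 0.5, 0.4], [1, 0, 0])


class TestBoostedModel:
    def test_separable_toy_set_training_auc_one(self, toy_model_data):
        X, y, _ = toy_model_data
        config = ModelConfig(n_folds=3, n_repeats=1, nrounds=50)
        booster = fit_boosted_model(X, y, config)
        import xgboost as xgb
        p = booster.predict(xgb.DMatrix(X))
        assert merged_auc(p, y) == 1.0

    def test_max_depth_two_dump_structural(self, toy_model_data):
        X, y, _ = toy_model_data
        booster = fit_boosted_model(X, y, ModelConfig(nrounds=30))
        for tree_json in booster.get_dump(dump_format="json"):
            def depth(node):
                if "leaf" in node:
                    return 0
                return 1 + max(depth(c) for c in node["children"])
            assert depth(json.loads(tree_json)) <= 2

    def test_one_class_labels_error(self, toy_model_data):
        X, _, _ = toy_model_data
        with pytest.raises(ValueError, match="single class"):
            fit_boosted_model(X, np.zeros(len(X), int), ModelConfig())

    def test_permuted_labels_cv_auc_near_half(self, toy_model_data):
        X, y, groups = toy_model_data
        rng = np.random.default_rng(0)
        # permute labels at subject level so grouping stays honest
        subjects = np.unique(groups)
        subj_label = {s: int(rng.random() < 0.2) for s in subjects}
        y_perm = np.array([subj_label[g] for g in groups])
        if y_perm.sum() == 0:
            y_perm[:4] = 1
        config = ModelConfig(n_folds=5, n_repeats=3, nrounds=40, seed=1)
        cv = repeated_group_cv(X, y_perm, groups, config)
        assert 0.35 <= cv.mean_auc <= 0.65

    def test_cv_scores_each_window_once_and_is_deterministic(self, toy_model_data):
        X, y, groups = toy_model_data
        config = ModelConfig(n_folds=4, n_repeats=2, nrounds=20, seed=5)
        cv1 = repeated_group_cv(X, y, groups, config)
        cv2 = repeated_group_cv(X, y, groups, config)
        assert not np.isnan(cv1.oof).any()
        assert cv1.aucs == cv2.aucs
        np.testing.assert_array_equal(cv1.oof, cv2.oof)

    def test_train_validation_subject_disjointness(self, toy_model_data):
        X, y, groups = toy_model_data
        config = ModelConfig(n_folds=4, n_repeats=2, nrounds=5, seed=2)
        cv = repeated_group_cv(X, y, groups, config)
        for fold_of in cv.fold_maps:
            folds = np.array([fold_of[int(g)] for g in groups])
            for k in range(config.n_folds):
                assert not (set(groups[folds == k]) & set(groups[folds != k]))


class TestSelection:
    def test_grid_search_prefers_separating_configuration(self, toy_model_data):
        from wearisk.risk_model import grid_search
        X, y, groups = toy_model_data
        config = ModelConfig(n_folds=4, nrounds=30, seed=0)
        grid = {"max_depth": [1, 2], "class_weight": [1.0, 10.0]}
        best, table = grid_search(X, y, groups, config, grid=grid, n_repeats=1)
        assert len(table) == 4
        assert set(table.columns) >= {"max_depth", "class_weight", "mean_auc"}
        assert table["mean_auc"].iloc[0] == table["mean_auc"].max()
        assert best.max_depth in (1, 2)
        # tie-break prefers the simpler (shallower) model
        ties = table[table["mean_auc"] == table["mean_auc"].max()]
        assert best.max_depth == ties["max_depth"].min()

    def test_select_nrounds_early_stopping(self, toy_model_data):
        from wearisk.risk_model import select_nrounds
        X, y, groups = toy_model_data
        config = ModelConfig(n_folds=4, seed=0)
        n = select_nrounds(X, y, groups, config, max_rounds=200, patience=10)
        assert 1 <= n <= 200


class TestThresholdGrouping:
    def test_reported_grouping_counts_and_rates(self):
        # 13 onsets among 7,592 high-risk vs 11 among 30,264 low-risk windows
        y = np.zeros(37856, int)
        p = np.full(37856, 0.001)
        p[:7592] = 0.02
        y[:13] = 1
        y[7592:7603] = 1
        comp = threshold_grouping(p, y, 0.01)
        assert (comp.n_high, comp.x_high) == (7592, 13)
        assert (comp.n_low, comp.x_low) == (30264, 11)
        assert round(100 * comp.prop_high, 2) == 0.17
        assert round(100 * comp.prop_low, 2) == 0.04
        assert comp.p_value < 0.001

    def test_all_below_threshold_flagged_degenerate(self):
        comp = threshold_grouping([0.001, 0.002], [0, 1], 0.5)
        assert comp.degenerate and np.isnan(comp.p_value)

    def test_identical_rates_give_p_one(self):
        y = np.array([1] + [0] * 9 + [1] + [0] * 9)
        p = np.array([0.9] * 10 + [0.1] * 10)
        comp = threshold_grouping(p, y, 0.5)
        assert comp.p_value == pytest.approx(1.0)


class TestFisherExact:
    def test_identical_rows_p_one(self):
        assert fisher_exact_two_sided(1, 9, 1, 9) == pytest.approx(1.0)

    def test_diagonal_two_by_two_enumeration(self):
        # margins (2,2)/(2,2): extreme tables each have prob 1/6
        assert fisher_exact_two_sided(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_zero_margin_is_one(self):
        assert fisher_exact_two_sided(0, 5, 0, 9) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    @pytest.mark.parametrize("seed", range(8))
    def test_exhaustive_enumeration_oracle_small_tables(self, seed):
        from math import comb
        rng = np.random.default_rng(seed)
        while True:
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if a + b + c + d <= 40 and (a + b) and (c + d) and (a + c) and (b + d):
                break
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2

        def pmf(k):
            return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

        p_obs = pmf(a)
        total = sum(pmf(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                    if pmf(k) <= p_obs * (1 + 1e-7))
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(total, rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [(7, 4546, 2, 7324), (4, 20467, 17, 10436), (22, 37754, 2, 78),
         (13, 7579, 11, 30253), (0, 14367, 3, 1105)],
    )
    def test_matches_scipy_on_study_scale_tables(self, table):
        a, b, c, d = table
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], rel=1e-6)

    def test_large_support_logspace_path(self):
        a, b, c, d = 5000, 5000, 4900, 5100
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], rel=1e-4)
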