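"""Fold planning, leave-one-run-out decoding, transfer, merging, and RFE."""

import numpy as np
import pytest

from cuefuse import (
    DecodingResult,
    PatternMatrix,
    cross_cue_decode,
    cross_decode_one_direction,
    cv_decode,
    dataset_to_patterns,
    merge_decoding_results,
    plan_folds,
    rfe_select,
)


def _pm(patterns, conditions, signs, run_ids):
    patterns = np.asarray(patterns, dtype=float)
    return PatternMatrix(
        patterns=patterns,
        conditions=np.asarray(conditions, dtype=object),
        signs=np.asarray(signs, dtype=int),
        run_ids=np.asarray(run_ids, dtype=int),
        voxel_ids=np.arange(patterns.shape[1]),
    )


def _separable_pm(n_runs=4, per_class=3, n_vox=6, gap=4.0, seed=0):
    """Linearly separable near/far patterns for one condition per run."""
    rng = np.random.default_rng(seed)
    pats, signs, runs = [], [], []
    direction = np.ones(n_vox)
    for r in range(n_runs):
        for s in (+1, -1):
            for _ in range(per_class):
                pats.append(s * gap * direction + rng.normal(0, 0.5, n_vox))
                signs.append(s)
                runs.append(r)
    n = len(pats)
    return _pm(pats, ["disparity"] * n, signs, runs)


class TestFoldPlan:
    def test_each_run_tests_once(self):
        plan = plan_folds([0, 0, 1, 2, 2, 3])
        assert plan.n_folds == 4
        assert plan.run_ids == (0, 1, 2, 3)
        for train, test in plan.folds:
            assert test not in train
            assert len(train) == 3

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            plan_folds([0, 0, 0])


class TestCvDecode:
    def test_separable_data_decodes_perfectly(self):
        pm = _separable_pm()
        res = cv_decode(pm, "disparity", plan_folds(pm.run_ids))
        assert res.accuracy == 1.0
        assert res.n_test_patterns == 4 * 6

    def test_global_label_flip_is_relearned(self):
        # flipping train AND test labels together is just a relabeling; the
        # classifier learns the flipped mapping and accuracy is unchanged
        pm = _separable_pm()
        plan = plan_folds(pm.run_ids)
        res = cv_decode(pm, "disparity", plan, signs=-pm.signs)
        assert res.accuracy == 1.0

    def test_training_label_flip_inverts_accuracy(self):
        # flipping only the training labels makes every prediction wrong
        pm = _separable_pm()
        plan = plan_folds(pm.run_ids)
        res = cross_decode_one_direction(
            pm, "disparity", "disparity", plan, train_signs=-pm.signs
        )
        assert res.accuracy == 0.0

    def test_zero_decision_value_scored_as_error(self):
        # symmetric training -> zero intercept; all-zero test pattern sits on
        # the boundary and must not count as correct
        pats = [[1.0, 1.0], [-1.0, -1.0], [1.0, 1.0], [-1.0, -1.0],
                [0.0, 0.0], [0.0, 0.0]]
        pm = _pm(pats, ["motion"] * 6, [1, -1, 1, -1, 1, -1],
                 [0, 0, 1, 1, 2, 2])
        res = cv_decode(pm, "motion", plan_folds(pm.run_ids))
        fold_for_run2 = list(plan_folds(pm.run_ids).run_ids).index(2)
        assert res.per_fold_accuracies[fold_for_run2] == 0.0

    def test_missing_class_in_training_rejected(self):
        pats = [[1.0], [1.0], [-1.0], [1.0]]
        pm = _pm(pats, ["motion"] * 4, [1, 1, -1, 1], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="missing class"):
            cv_decode(pm, "motion", plan_folds(pm.run_ids))

    def test_accuracy_is_count_weighted_fold_mean(self):
        res = DecodingResult(
            condition="x", direction="within",
            per_fold_accuracies=np.array([1.0, 0.5]),
            per_fold_counts=np.array([6, 2]),
        )
        assert res.accuracy == pytest.approx((6 * 1.0 + 2 * 0.5) / 8)


class TestCrossDecode:
    def test_shared_code_transfers_across_conditions(self, rng):
        pats, conds, signs, runs = [], [], [], []
        direction = np.ones(5)
        for r in range(4):
            for cond in ("disparity", "motion"):
                for s in (+1, -1):
                    for _ in range(2):
                        pats.append(s * 3.0 * direction + rng.normal(0, 0.4, 5))
                        conds.append(cond)
                        signs.append(s)
                        runs.append(r)
        pm = _pm(pats, conds, signs, runs)
        cross = cross_cue_decode(pm, "disparity", "motion", plan_folds(pm.run_ids))
        assert cross.d_to_m.accuracy == 1.0
        assert cross.m_to_d.accuracy == 1.0
        assert cross.mean.accuracy == 1.0
        assert cross.mean.n_test_patterns == (
            cross.d_to_m.n_test_patterns + cross.m_to_d.n_test_patterns
        )


class TestMergeResults:
    def test_fold_concatenation_and_pooled_accuracy(self):
        a = DecodingResult("c", "within", np.array([0.8, 0.6]), np.array([5, 5]))
        b = DecodingResult("c", "within", np.array([1.0]), np.array([10]))
        m = merge_decoding_results([a, b])
        assert m.per_fold_accuracies.tolist() == [0.8, 0.6, 1.0]
        assert m.n_test_patterns == 20
        assert m.accuracy == pytest.approx((0.8 * 5 + 0.6 * 5 + 1.0 * 10) / 20)

    def test_mixed_conditions_rejected(self):
        a = DecodingResult("c", "within", np.array([0.8]), np.array([5]))
        b = DecodingResult("d", "within", np.array([0.8]), np.array([5]))
        with pytest.raises(ValueError):
            merge_decoding_results([a, b])


class TestRfe:
    def test_subsets_respect_floor_and_training_only(self, tiny_dataset):
        pm = dataset_to_patterns(tiny_dataset, cap=None)
        plan = plan_folds(pm.run_ids)
        subsets = rfe_select(pm, "congruent", plan, floor_count=12)
        assert len(subsets) == plan.n_folds
        for sub in subsets:
            assert sub.size == 12
            assert np.all(np.diff(sub) > 0)  # sorted, unique positions
            assert sub.max() < pm.n_voxels

    def test_floor_at_or_above_voxel_count_is_identity(self, tiny_dataset):
        pm = dataset_to_patterns(tiny_dataset, cap=10)
        plan = plan_folds(pm.run_ids)
        subsets = rfe_select(pm, "congruent", plan, floor_count=50)
        for sub in subsets:
            np.testing.assert_array_equal(sub, np.arange(pm.n_voxels))

    def test_elimination_step_drops_smallest_weight_fraction(self):
        # 100 -> 90 -> 81 -> ... first step must remove exactly 10 voxels
        rng = np.random.default_rng(1)
        pats, signs, runs = [], [], []
        for r in range(3):
            for s in (+1, -1):
                for _ in range(4):
                    base = np.zeros(100)
                    base[:5] = s * 3.0  # informative voxels survive
                    pats.append(base + rng.normal(0, 0.3, 100))
                    signs.append(s)
                    runs.append(r)
        pm = _pm(pats, ["congruent"] * len(pats), signs, runs)
        subsets = rfe_select(pm, "congruent", plan_folds(pm.run_ids),
                             step_fraction=0.1, floor_count=50)
        for sub in subsets:
            assert sub.size == 50
            assert set(range(5)) <= set(sub.tolist())
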