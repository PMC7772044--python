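"""Cascade fusion, OOB permutation importance, and sequential forward selection."""

import numpy as np
import pytest

import masstex as mt
from masstex.block import FeatureBlock
from masstex.errors import AlignmentError, ConfigurationError, DegenerateLabelsError


def _block(name, n, d, seed=0):
    vals = np.random.default_rng(seed).normal(size=(n, d))
    return FeatureBlock(name, vals, [f"{name}_{i}" for i in range(d)])


class TestCascadeFuse:
    def test_dims_add_and_order_preserved(self):
        a, b, c = _block("a", 5, 2), _block("b", 5, 3), _block("c", 5, 4)
        fused = mt.cascade_fuse([a, b, c])
        assert fused.length == 9
        assert fused.columns == a.columns + b.columns + c.columns
        np.testing.assert_array_equal(fused.values[:, :2], a.values)
        np.testing.assert_array_equal(fused.values[:, 5:], c.values)
        assert fused.provenance == ["a"] * 2 + ["b"] * 3 + ["c"] * 4

    def test_single_block_identity(self):
        a = _block("a", 4, 3)
        assert mt.cascade_fuse([a]) is a

    def test_row_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            mt.cascade_fuse([_block("a", 5, 2), _block("b", 6, 2)])


def _labeled_data(n=60, n_noise=20, seed=0):
    """A binary label, one feature equal to the label, and pure-noise features."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y.astype(float),
                         rng.normal(size=(n, n_noise))])
    return X, y


class TestOobImportance:
    def test_single_tree_importance_is_plain_difference(self):
        X, y = _labeled_data(n=30, n_noise=3, seed=1)
        rank = mt.oob_importance(X, y, m_trees=1, seed=4)
        expected = rank.per_tree_acc[0] - rank.per_tree_perm_acc[0]
        np.testing.assert_array_equal(rank.importance, expected)

    def test_importance_recomputable_from_audit_trail(self):
        X, y = _labeled_data(n=40, n_noise=5, seed=2)
        rank = mt.oob_importance(X, y, m_trees=3, seed=0)
        np.testing.assert_allclose(rank.importance, rank.recompute_importance(),
                                   atol=1e-12)

    def test_label_identical_feature_ranks_first(self):
        X, y = _labeled_data(n=60, n_noise=50, seed=3)
        rank = mt.oob_importance(X, y, m_trees=100, seed=0)
        assert rank.ranking[0] == 0
        assert sorted(rank.ranking) == list(range(51))  # a permutation

    def test_pure_noise_importance_concentrates_near_zero(self):
        for seed in range(3):
            X, y = _labeled_data(n=60, n_noise=10, seed=seed)
            rank = mt.oob_importance(X, y, m_trees=200, seed=seed)
            assert np.abs(rank.importance[1:]).max() <= 0.05

    def test_permutation_null_destroys_structure(self):
        """Max importance under permuted labels falls below the intact
        label-copy feature's importance (structure, not noise, drives D_i)."""
        X, y = _labeled_data(n=60, n_noise=10, seed=5)
        intact = mt.oob_importance(X, y, m_trees=100, seed=0)
        y_perm = np.random.default_rng(7).permutation(y)
        null = mt.oob_importance(X, y_perm, m_trees=100, seed=0)
        assert null.importance.max() < intact.importance[0]

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            mt.oob_importance(np.zeros((10, 2)), np.zeros(10), m_trees=2)


class TestSfsSelect:
    def test_predictive_feature_selected_and_accuracy_kept(self):
        for seed in range(3):
            X, y = _labeled_data(n=60, n_noise=10, seed=seed)
            rank = mt.oob_importance(X, y, m_trees=50, seed=seed)
            sel = mt.sfs_select(rank, X, y, seed=seed)
            assert 0 in sel.selected_indices
            from sklearn.ensemble import RandomForestClassifier
            from masstex.fusion import _cv_accuracy
            est = RandomForestClassifier(n_estimators=100, random_state=seed)
            full = _cv_accuracy(est, X, y, 5, seed)
            kept = _cv_accuracy(est, X[:, sel.selected_indices], y, 5, seed)
            assert kept >= full - 0.02

    def test_all_identical_features_keep_exactly_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=40)
        X = np.tile(col[:, None], (1, 5))
        y = (col > 0).astype(int)
        rank = mt.oob_importance(X, y, m_trees=20, seed=0)
        sel = mt.sfs_select(rank, X, y, seed=0)
        assert len(sel.selected_indices) == 1

    def test_infinite_tolerance_keeps_only_top_ranked(self):
        X, y = _labeled_data(n=40, n_noise=6, seed=1)
        rank = mt.oob_importance(X, y, m_trees=20, seed=0)
        sel = mt.sfs_select(rank, X, y, seed=0, tolerance=np.inf)
        assert sel.selected_indices == [int(rank.ranking[0])]
        assert len(sel.cv_curve) == len(sel.considered) == X.shape[1]

    def test_too_many_folds_rejected(self):
        X, y = _labeled_data(n=8, n_noise=2, seed=0)
        rank = mt.oob_importance(X, y, m_trees=5, seed=0)
        with pytest.raises(ConfigurationError):
            mt.sfs_select(rank, X, y, k_folds=10)


class TestFuseAfterReduction:
    def test_selected_dims_add_with_provenance(self):
        Xa, y = _labeled_data(n=40, n_noise=6, seed=0)
        Xb, _ = _labeled_data(n=40, n_noise=4, seed=1)
        ta = FeatureBlock("texton", Xa, [f"t{i}" for i in range(7)])
        db = FeatureBlock("deep", Xb, [f"d{i}" for i in range(5)])
        params = mt.ReductionParams(importance_trees=30, sfs_trees=30, seed=0)
        fused = mt.fuse_after_reduction(ta, db, y, params)
        n_t = len(fused.selections["texton"].selected_indices)
        n_d = len(fused.selections["deep"].selected_indices)
        assert fused.block.length == n_t + n_d
        assert fused.block.provenance == ["texton"] * n_t + ["deep"] * n_d
        # determinism
        again = mt.fuse_after_reduction(ta, db, y, params)
        np.testing.assert_array_equal(fused.block.values, again.block.values)

    def test_empty_block_degenerates_with_warning(self):
        X, y = _labeled_data(n=40, n_noise=4, seed=2)
        full = FeatureBlock("texton", X, [f"t{i}" for i in range(5)])
        empty = FeatureBlock("deep", np.empty((40, 0)), [])
        params = mt.ReductionParams(importance_trees=20, sfs_trees=20, seed=0)
        with pytest.warns(UserWarning):
            fused = mt.fuse_after_reduction(full, empty, y, params)
        assert set(fused.block.provenance) == {"texton"}
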