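"""Regression tree growth, pruning semantics, prediction and leave-one-out."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from cholestage import (
    SampleTable,
    build_sample_table,
    fit_tree,
    log_time,
    loo_evaluate,
    predict_time,
)
from cholestage.phase_tree import best_split, predict_matrix
from _oracles import naive_best_split, naive_tree


def _table(X, y, times=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    times = np.asarray(times if times is not None else np.exp(y) - 1)
    return SampleTable(
        X,
        y,
        [f"c{j + 1}" for j in range(X.shape[1])],
        times,
        np.ones(len(y), dtype=int),
    )


def _grid_table(seed=0, n_pred=3, noise=0.3):
    """40-sample study-grid table with noisy monotone predictors."""
    rng = np.random.default_rng(seed)
    times = np.repeat([0, 6, 12, 18, 30, 48, 120, 336], 5)
    y = log_time(times)
    X = np.column_stack(
        [y * rng.uniform(0.5, 1.5) + rng.normal(0, noise, y.size)
         for _ in range(n_pred)]
    )
    return _table(X, y, times)


def _tree_nodes(node):
    if node.is_leaf:
        return [node]
    return [node] + _tree_nodes(node.left) + _tree_nodes(node.right)


def _assert_same_tree(node, ref):
    """Compare a fitted tree with the oracle's nested-dict tree."""
    assert node.n == ref["n"]
    assert node.prediction == pytest.approx(ref["prediction"])
    if "predictor" in ref:
        assert not node.is_leaf
        assert node.predictor == ref["predictor"]
        assert node.threshold == pytest.approx(ref["threshold"])
        _assert_same_tree(node.left, ref["left"])
        _assert_same_tree(node.right, ref["right"])
    else:
        assert node.is_leaf


class TestSampleTable:
    def test_study_grid_dimensions_and_response(self, study_clustered):
        _, norm, _, clusters = study_clustered
        table = build_sample_table(clusters, norm)
        assert table.n_samples == 40
        assert table.X.shape == (40, 6)
        # response anchors: t=0 -> 0, t=48 -> log 49
        assert table.y[table.times_h == 0][0] == pytest.approx(0.0)
        assert table.y[table.times_h == 48][0] == pytest.approx(np.log(49))

    def test_singleton_clusters_expose_raw_factors(self):
        import cholestage as cs

        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 8, 5))
        data = cs.TimeCourseDataset(
            [cs.FactorMeta(f"f{i}", "B", "none") for i in range(3)],
            [0, 6, 12, 18, 30, 48, 120, 336],
            vals,
        )
        norm = cs.normalize_factors(data)
        sim = cs.similarity_matrix(norm)
        clusters = cs.cluster_factors(sim, 3, norm)
        table = build_sample_table(clusters, norm)
        for j, c in enumerate(clusters.cluster_labels):
            member = clusters.members(c)[0]
            np.testing.assert_allclose(
                table.X[:, j], norm.factor_values(member).ravel()
            )


class TestFitTree:
    def test_two_group_perfect_separation(self):
        X = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        tree = fit_tree(_table(X, y))
        assert not tree.root.is_leaf
        assert tree.root.threshold == pytest.approx(0.5)
        assert tree.root.left.prediction == pytest.approx(0.0)
        assert tree.root.right.prediction == pytest.approx(1.0)
        assert tree.n_leaves == 2

    def test_constant_response_single_leaf(self):
        X = np.arange(10.0)[:, None]
        tree = fit_tree(_table(X, np.ones(10), times=np.zeros(10) + 1))
        assert tree.root.is_leaf

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [12, 40, 60])
    def test_matches_exhaustive_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = X[:, 0] * 2 + np.sin(X[:, 1]) + rng.normal(0, 0.5, n)
        tree = fit_tree(_table(X, y, times=np.abs(y)))
        ref = naive_tree(X, y, minsplit=6, minbucket=2, cp=0.01)
        _assert_same_tree(tree.root, ref)

    def test_best_split_agrees_with_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = rng.normal(size=(25, 4))
            y = rng.normal(size=25)
            ours = best_split(X, y, minbucket=2)
            ref = naive_best_split(X, y, minbucket=2)
            if ref is None:
                assert ours is None
                continue
            assert ours[0] == ref[0]
            assert ours[1] == pytest.approx(ref[1])
            assert ours[2] == pytest.approx(ref[2])

    def test_interpolation_limit(self):
        rng = np.random.default_rng(2)
        x = rng.permutation(20).astype(float)
        y = rng.normal(size=20)
        tree = fit_tree(
            _table(x[:, None], y, times=np.abs(y)),
            minsplit=2,
            minbucket=1,
            cp=0.0,
        )
        pred = predict_matrix(tree, x[:, None])
        np.testing.assert_allclose(pred, y, atol=1e-12)

    def test_accepted_splits_strictly_reduce_sse(self):
        table = _grid_table(seed=3)
        tree = fit_tree(table)

        def node_sse(node, rows):
            y = table.y[rows]
            return ((y - y.mean()) ** 2).sum()

        def check(node, rows):
            if node.is_leaf:
                return
            left = rows[table.X[rows, node.predictor] <= node.threshold]
            right = rows[table.X[rows, node.predictor] > node.threshold]
            assert node_sse(node.left, left) + node_sse(node.right, right) < (
                node_sse(node, rows) - 1e-12
            )
            check(node.left, left)
            check(node.right, right)

        check(tree.root, np.arange(table.n_samples))

    def test_minbucket_respected(self):
        table = _grid_table(seed=4)
        tree = fit_tree(table, minbucket=4)
        assert all(leaf.n >= 4 for leaf in tree.leaves())

    @pytest.mark.parametrize("seed", range(4))
    def test_root_split_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(seed + 100)
        X = rng.normal(size=(40, 3))
        y = 1.5 * X[:, 1] + rng.normal(0, 0.4, 40)
        tree = fit_tree(_table(X, y, times=np.abs(y)), cp=0.0)
        sk = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        assert tree.root.predictor == sk.tree_.feature[0]
        # sklearn computes thresholds in float32
        assert tree.root.threshold == pytest.approx(
            sk.tree_.threshold[0], rel=1e-6
        )


class TestPrediction:
    def test_single_leaf_predicts_training_mean(self):
        X = np.zeros((10, 2))
        y = np.linspace(0, 1, 10)
        tree = fit_tree(_table(X, y, times=np.abs(y)))
        t_log, hours, label = predict_time(tree, [5.0, -5.0])
        assert t_log == pytest.approx(y.mean())

    def test_hand_traced_routing(self):
        # three leaves: x0 <= 0.5 ? (x1 <= -1 ? A : B) : C
        X = np.array(
            [[0.0, -2.0]] * 10 + [[0.0, 0.0]] * 10 + [[1.0, 0.0]] * 10
        )
        y = np.array([0.0] * 10 + [1.0] * 10 + [2.0] * 10)
        tree = fit_tree(_table(X, y, times=np.abs(y)))
        probes = {
            (0.2, -1.5): 0.0,
            (0.4, -9.0): 0.0,
            (0.5, 0.3): 1.0,
            (0.6, -3.0): 2.0,
            (9.9, 9.9): 2.0,
        }
        for x, expected in probes.items():
            t_log, _, _ = predict_time(tree, list(x))
            assert t_log == pytest.approx(expected)

    def test_dict_input_and_missing_predictor(self):
        X = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        tree = fit_tree(_table(X, y))
        t_log, _, _ = predict_time(tree, {"c1": 0.2})
        assert t_log == pytest.approx(0.0)
        with pytest.raises(ValueError, match="no surrogate"):
            predict_time(tree, [np.nan])

    def test_class_labels_back_transform(self):
        table = _grid_table(seed=0, noise=0.05)
        tree = fit_tree(table)
        for leaf in tree.leaves():
            assert leaf.predicted_hours == pytest.approx(
                np.exp(leaf.prediction) - 1
            )
            assert leaf.class_label.endswith(("h", "d"))

    def test_render_and_json_round(self):
        table = _grid_table(seed=1)
        tree = fit_tree(table)
        text = tree.render()
        assert "leaf" in text and "<=" in text
        import json

        d = json.loads(tree.to_json())
        assert d["cp"] == 0.01 and "root" in d


class TestLeaveOneOut:
    def test_one_prediction_per_sample(self):
        table = _grid_table(seed=6)
        report = loo_evaluate(table)
        assert report.n_samples == 40
        assert sorted(report.records["sample"]) == list(range(40))

    def test_constant_response_predicts_grand_mean(self):
        X = np.random.default_rng(0).normal(size=(12, 2))
        y = np.full(12, 2.5)
        report = loo_evaluate(_table(X, y, times=np.exp(y) - 1))
        np.testing.assert_allclose(report.records["pred_log"], 2.5)
        assert report.d == pytest.approx(0.0)

    def test_perfectly_separable_classes_recovered(self):
        # two time classes with a >=10x gap between predictor spread and
        # class separation
        rng = np.random.default_rng(1)
        times = np.repeat([0, 48], 10)
        y = log_time(times)
        x = np.where(times == 0, 0.0, 10.0) + rng.normal(0, 0.5, 20)
        report = loo_evaluate(_table(x[:, None], y, times=times))
        assert (
            report.records["pred_nearest_time_h"] == report.records["time_h"]
        ).all()
        assert report.d == pytest.approx(0.0)
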