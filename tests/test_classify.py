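"""Decision-tree learning, the fixed published tree, KNN and evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soynose.classify import (
    ConfusionMatrix,
    TreeNode,
    evaluate,
    exhaustive_tree_accuracy,
    knn_classify,
    reference_tree,
    split_by_plants,
    train_tree,
    training_accuracy,
)


class TestReferenceTree:
    @pytest.mark.parametrize(
        "features,expected",
        [
            ({"regression_max_sensor_6": 0.5, "max_sensor_6": 0.2}, "irrigated"),
            ({"regression_max_sensor_6": 0.5, "max_sensor_6": 0.4}, "non_irrigated"),
            ({"regression_max_sensor_6": 0.9, "regression_temperature_int": 0.5}, "irrigated"),
            ({"regression_max_sensor_6": 0.9, "regression_temperature_int": 0.8}, "non_irrigated"),
        ],
    )
    def test_routing(self, features, expected):
        assert reference_tree().predict(features) == expected

    def test_boundary_values_route_left(self):
        tree = reference_tree()
        assert tree.predict({"regression_max_sensor_6": 0.829849,
                             "max_sensor_6": 0.315273}) == "irrigated"
        assert tree.predict({"regression_max_sensor_6": 0.8298491,
                             "regression_temperature_int": 0.714568}) == "irrigated"

    def test_invariant_to_unused_features(self):
        features = {"regression_max_sensor_6": 0.5, "max_sensor_6": 0.2,
                    "lux_ext": 1e9, "anything": -5.0}
        assert reference_tree().predict(features) == "irrigated"

    def test_missing_feature_raises(self):
        with pytest.raises(KeyError):
            reference_tree().predict({"max_sensor_6": 0.2})

    def test_structure(self):
        tree = reference_tree()
        assert tree.depth() == 2
        assert tree.n_leaves() == 4


def toy_frame(values, name="x"):
    return pd.DataFrame({name: values})


class TestTrainTree:
    def test_pure_data_gives_single_leaf(self):
        tree = train_tree(toy_frame([1.0, 2.0, 3.0]), ["irrigated"] * 3, min_leaf=1)
        assert tree.is_leaf and tree.klass == "irrigated"

    def test_perfect_1d_split_at_midpoint(self):
        X = toy_frame([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        y = ["irrigated"] * 3 + ["non_irrigated"] * 3
        tree = train_tree(X, y, min_leaf=1)
        assert tree.feature == "x"
        assert tree.threshold == pytest.approx(0.5)
        assert tree.left.klass == "irrigated" and tree.right.klass == "non_irrigated"

    def test_learned_threshold_between_closest_opposite_points(self, rng):
        for _ in range(20):
            xi = np.sort(rng.uniform(size=8))
            cut = rng.integers(1, 8)
            y = ["irrigated"] * cut + ["non_irrigated"] * (8 - cut)
            tree = train_tree(toy_frame(xi), y, min_leaf=1, max_depth=1)
            if tree.is_leaf:
                continue
            assert xi[cut - 1] < tree.threshold < xi[cut]

    def test_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = np.where(rng.uniform(size=30) < 0.5, "irrigated", "non_irrigated")
        tree = train_tree(X, y, min_leaf=2)
        perm = rng.permutation(30)
        tree2 = train_tree(X.iloc[perm].reset_index(drop=True), y[perm], min_leaf=2)
        assert tree.to_dict() == tree2.to_dict()

    def test_depth_and_min_leaf_respected(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = np.where(rng.uniform(size=50) < 0.5, "irrigated", "non_irrigated")
        tree = train_tree(X, y, max_depth=2, min_leaf=5)
        assert tree.depth() <= 2

    def test_errors(self):
        with pytest.raises(ValueError):
            train_tree(toy_frame([]), [])
        with pytest.raises(ValueError):
            train_tree(toy_frame([1.0]), ["irrigated"], min_leaf=2)
        with pytest.raises(ValueError):
            train_tree(pd.DataFrame(index=[0]), ["irrigated"])

    def test_matches_exhaustive_oracle_on_random_data(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 21))
            f = int(rng.integers(1, 4))
            X = pd.DataFrame(rng.normal(size=(n, f)), columns=[f"f{j}" for j in range(f)])
            y = np.where(rng.uniform(size=n) < 0.5, "irrigated", "non_irrigated")
            tree = train_tree(X, y, max_depth=None, min_leaf=1)
            assert training_accuracy(tree, X, y) == pytest.approx(
                exhaustive_tree_accuracy(X, y)
            )

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
            y = np.where(rng.uniform(size=20) < 0.5, "irrigated", "non_irrigated")
            ours = train_tree(X, y, max_depth=None, min_leaf=1)
            clf = sklearn_tree.DecisionTreeClassifier(criterion="entropy", random_state=0)
            clf.fit(X, y)
            assert training_accuracy(ours, X, y) == pytest.approx(clf.score(X, y))


class TestSerialization:
    def test_round_trip_dict(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = np.where(X["a"] + X["b"] > 0, "irrigated", "non_irrigated")
        tree = train_tree(X, y, min_leaf=2)
        clone = TreeNode.from_dict(tree.to_dict())
        rows = X.to_dict(orient="records")
        assert [tree.predict(r) for r in rows] == [clone.predict(r) for r in rows]

    def test_save_load_file(self, tmp_path):
        tree = reference_tree()
        path = tmp_path / "model.json"
        tree.save(path)
        clone = TreeNode.load(path)
        assert clone.to_dict() == tree.to_dict()

    def test_invalid_nodes_rejected(self):
        with pytest.raises(ValueError):
            TreeNode(feature="x", threshold=0.5)  # missing children
        with pytest.raises(ValueError):
            TreeNode(klass="irrigated", feature="x")


class TestKnn:
    def train_set(self):
        X = pd.DataFrame({"a": [0.0, 0.1, 0.9, 1.0, 0.5], "b": [0.0, 0.0, 1.0, 1.0, 0.4]})
        y = ["irrigated", "irrigated", "non_irrigated", "non_irrigated", "irrigated"]
        return X, y

    def test_k1_exact_point(self):
        X, y = self.train_set()
        assert knn_classify(X, y, {"a": 0.9, "b": 1.0}, k=1) == "non_irrigated"

    def test_k_equals_n_majority(self):
        X, y = self.train_set()
        assert knn_classify(X, y, {"a": 0.5, "b": 0.5}, k=5) == "irrigated"

    def test_k3_matches_exhaustive_sort_oracle(self, rng):
        X, y = self.train_set()
        for _ in range(25):
            q = {"a": float(rng.uniform()), "b": float(rng.uniform())}
            d = np.sqrt((X["a"] - q["a"]) ** 2 + (X["b"] - q["b"]) ** 2).to_numpy()
            order = np.argsort(d, kind="stable")[:3]
            votes = {}
            for i in order:
                votes[y[i]] = votes.get(y[i], 0) + 1
            top = max(votes.values())
            tied = [c for c, v in votes.items() if v == top]
            if len(tied) == 1:
                assert knn_classify(X, y, q, k=3) == tied[0]

    def test_vote_tie_breaks_by_distance_sum(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        y = ["non_irrigated", "irrigated"]
        # query closer to the non_irrigated point: its distance sum is smaller
        assert knn_classify(X, y, {"a": 0.4}, k=2) == "non_irrigated"

    def test_matches_sklearn_cross_check(self, rng):
        neighbors = pytest.importorskip("sklearn.neighbors")
        X = pd.DataFrame(rng.uniform(size=(40, 3)), columns=["a", "b", "c"])
        y = np.where(rng.uniform(size=40) < 0.5, "irrigated", "non_irrigated")
        clf = neighbors.KNeighborsClassifier(n_neighbors=3)
        clf.fit(X, y)
        agreements = 0
        for _ in range(20):
            q = rng.uniform(size=3)
            ours = knn_classify(X, list(y), q, k=3)
            theirs = clf.predict(pd.DataFrame([q], columns=X.columns))[0]
            agreements += ours == theirs
        assert agreements >= 19  # ties may legitimately differ

    def test_errors(self):
        X, y = self.train_set()
        with pytest.raises(ValueError):
            knn_classify(X, y, {"a": 0.0, "b": 0.0}, k=6)
        with pytest.raises(ValueError):
            knn_classify(X.iloc[:0], [], {"a": 0.0, "b": 0.0}, k=1)


class TestConfusionMatrix:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix.from_predictions(
            ["irrigated", "non_irrigated"], ["irrigated", "non_irrigated"]
        )
        assert np.allclose(np.diag(cm.row_percent), 100.0)
        assert cm.accuracy_pct == 100.0

    def test_constant_predictor_on_balanced_test(self):
        y_true = ["irrigated"] * 5 + ["non_irrigated"] * 5
        cm = ConfusionMatrix.from_predictions(y_true, ["irrigated"] * 10)
        assert np.allclose(cm.row_percent, [[100.0, 0.0], [100.0, 0.0]])
        assert cm.accuracy_pct == pytest.approx(50.0)

    def test_hand_tallied_counts(self):
        y_true = ["irrigated"] * 6 + ["non_irrigated"] * 4
        y_pred = ["irrigated"] * 4 + ["non_irrigated"] * 2 + ["non_irrigated"] * 3 + ["irrigated"]
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        assert cm.counts.tolist() == [[4, 2], [1, 3]]
        assert cm.accuracy_pct == pytest.approx(70.0)

    def test_rows_sum_to_100(self, rng):
        y_true = np.where(rng.uniform(size=50) < 0.4, "irrigated", "non_irrigated")
        y_pred = np.where(rng.uniform(size=50) < 0.6, "irrigated", "non_irrigated")
        cm = ConfusionMatrix.from_predictions(list(y_true), list(y_pred))
        sums = cm.row_percent.sum(axis=1)
        assert np.allclose(sums[np.isfinite(sums)], 100.0, atol=0.1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix.from_predictions(["weird"], ["irrigated"])

    def test_summary_text(self):
        cm = ConfusionMatrix.from_predictions(["irrigated"], ["irrigated"])
        text = cm.summary()
        assert "irrigated" in text and "accuracy" in text


class TestEvaluate:
    def test_tree_and_callable_agree(self, rng):
        X = pd.DataFrame(rng.uniform(size=(20, 1)), columns=["x"])
        y = np.where(X["x"] > 0.5, "non_irrigated", "irrigated")
        tree = train_tree(X, y, min_leaf=1)
        cm_tree, acc_tree = evaluate(tree, X, y)
        cm_fn, acc_fn = evaluate(lambda r: tree.predict(r), X, y)
        assert acc_tree == acc_fn == 100.0
        assert cm_tree.counts.tolist() == cm_fn.counts.tolist()

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            evaluate(reference_tree(), pd.DataFrame(), [])


class TestSplitByPlants:
    def test_grouped_and_deterministic(self):
        plants = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        train_a, test_a = split_by_plants(plants, n_test=2, rng=42)
        train_b, test_b = split_by_plants(plants, n_test=2, rng=42)
        assert (train_a, test_a) == (train_b, test_b)
        assert set(train_a) | set(test_a) == {1, 2, 3, 4, 5}
        assert not set(train_a) & set(test_a)

    def test_invalid_n_test(self):
        with pytest.raises(ValueError):
            split_by_plants([1, 2, 3], n_test=3)
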