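"""Simpson impurity, bivariate split search and tree growth, with an
exhaustive brute-force oracle on small instances."""

import itertools

import numpy as np
import pytest

import inflammadx as ix
from inflammadx.bivariate import (
    DIV_EPS,
    IDENTITY,
    OPS,
    _candidate_list,
    best_bivariate_split,
    explain_bivariate,
    fit_bivariate_tree,
    predict_bivariate,
    simpson_impurity,
    tree_from_dict,
    tree_to_dict,
)
from inflammadx.exceptions import ValidationError


class TestSimpsonImpurity:
    def test_pure_node_zero(self):
        assert simpson_impurity([10, 0, 0]) == 0.0

    def test_two_balanced_classes(self):
        assert simpson_impurity([5, 5]) == pytest.approx(0.5)

    def test_three_class_hand_value(self):
        # 1 - (625 + 9 + 4) / 900
        assert simpson_impurity([25, 3, 2]) == pytest.approx(0.2911111111111111)

    def test_balanced_k_classes_hit_maximum(self):
        for K in (2, 3, 4, 5):
            assert simpson_impurity([7] * K) == pytest.approx(1 - 1 / K)

    def test_moving_mass_to_majority_decreases_impurity(self):
        base = simpson_impurity([6, 3, 1])
        assert simpson_impurity([7, 2, 1]) < base

    def test_empty_node_rejected(self):
        with pytest.raises(ValidationError):
            simpson_impurity([0, 0])


def oracle_best_split(X, y, min_leaf=1):
    """Exhaustive, slow enumeration of every candidate expression and
    threshold; same tie order as documented (impurity, identity-first,
    feature indices, op order, threshold)."""
    X = np.asarray(X, float)
    classes = sorted(set(y))
    codes = np.array([classes.index(v) for v in y])
    K = len(classes)
    n = len(X)
    parent = np.bincount(codes, minlength=K)
    best = None
    for rank, (i, j, op) in enumerate(_candidate_list(X.shape[1])):
        if op == IDENTITY:
            vals = X[:, i]
        elif op == "+":
            vals = X[:, i] + X[:, j]
        elif op == "-":
            vals = X[:, i] - X[:, j]
        elif op == "*":
            vals = X[:, i] * X[:, j]
        else:
            if np.any(np.abs(X[:, j]) < DIV_EPS):
                continue
            vals = X[:, i] / X[:, j]
        sv = np.sort(np.unique(vals))
        for a, b in zip(sv[:-1], sv[1:]):
            thr = (a + b) / 2
            left = codes[vals <= thr]
            right = codes[vals > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            w = (
                len(left) * simpson_impurity(np.bincount(left, minlength=K))
                + len(right) * simpson_impurity(np.bincount(right, minlength=K))
            ) / n
            key = (w, rank, thr)
            if best is None or key < (best[0] - 1e-12, best[1], best[2]) or (
                abs(key[0] - best[0]) <= 1e-12 and (key[1], key[2]) < (best[1], best[2])
            ):
                if best is None or key[0] < best[0] - 1e-12 or (
                    abs(key[0] - best[0]) <= 1e-12 and (key[1], key[2]) < (best[1], best[2])
                ):
                    best = (w, rank, thr, i, j, op)
    if best is None:
        return None
    parent_imp = simpson_impurity(parent)
    if best[0] >= parent_imp - 1e-12:
        return None
    return best


class TestBestBivariateSplit:
    def test_difference_rule_recovered_exactly(self):
        # class = sign(x1 - x2): separable only by the difference (or ratio)
        X = np.array(
            [[5.0, 1.0], [4.0, 2.0], [6.0, 3.0], [9.0, 7.0], [1.0, 5.0], [2.0, 4.0], [3.0, 6.0], [7.0, 9.0]]
        )
        y = ["hi", "hi", "hi", "hi", "lo", "lo", "lo", "lo"]
        split = best_bivariate_split(X, y)
        assert split.op == "-"
        assert {split.feature_i, split.feature_j} == {0, 1}
        # children are pure
        vals = X[:, split.feature_i] - X[:, split.feature_j]
        left = np.asarray(y, object)[vals <= split.threshold]
        assert len(set(left)) == 1

    def test_constant_features_give_none(self):
        X = np.ones((8, 3))
        y = ["a", "b"] * 4
        assert best_bivariate_split(X, y) is None

    def test_single_class_gives_none(self):
        X = np.arange(12.0).reshape(6, 2)
        assert best_bivariate_split(X, ["a"] * 6) is None

    def test_tie_broken_by_candidate_order(self):
        # two identical informative columns -> identical impurities; the
        # documented order prefers the lower feature index
        col = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([col, col])
        y = ["a", "a", "b", "b"]
        split = best_bivariate_split(X, y)
        assert split.op == IDENTITY and split.feature_i == 0

    def test_division_guard_skips_zero_denominators(self):
        X = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 0.5], [4.0, 2.0]])
        y = ["a", "a", "b", "b"]
        split = best_bivariate_split(X, y)
        assert not (split.op == "/" and split.feature_j == 1)

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        p = int(rng.integers(1, 4))
        X = rng.integers(1, 6, size=(n, p)).astype(float)
        y = list(rng.choice(["a", "b", "c"][: int(rng.integers(2, 4))], size=n))
        got = best_bivariate_split(X, y)
        expected = oracle_best_split(X, y)
        if expected is None:
            assert got is None
        else:
            w, rank, thr, i, j, op = expected
            assert (got.feature_i, got.feature_j, got.op) == (i, j, op)
            assert got.threshold == pytest.approx(thr)

    def test_chosen_split_never_increases_impurity(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X = rng.normal(size=(20, 3))
            y = list(rng.choice(["a", "b", "c"], size=20))
            split = best_bivariate_split(X, y)
            if split is None:
                continue
            codes = np.array([["a", "b", "c"].index(v) for v in y])
            parent = simpson_impurity(np.bincount(codes, minlength=3))
            if split.op == IDENTITY:
                vals = X[:, split.feature_i]
            else:
                a, b = X[:, split.feature_i], X[:, split.feature_j]
                vals = {"+": a + b, "-": a - b, "*": a * b, "/": a / b}[split.op]
            m = vals <= split.threshold
            w = (
                m.sum() * simpson_impurity(np.bincount(codes[m], minlength=3))
                + (~m).sum() * simpson_impurity(np.bincount(codes[~m], minlength=3))
            ) / len(y)
            assert w < parent


@pytest.fixture(scope="module")
def ratio_fixture():
    """Classes defined by a planted ratio with wide marginal overlap."""
    rng = np.random.default_rng(0)
    n = 30
    den = rng.lognormal(1.0, 0.8, size=2 * n)
    # both levels above 1 so no sum/difference/sign shortcut separates;
    # only the ratio has a clean margin
    levels = np.array([2.0] * n + [1.25] * n)
    num = levels * den * np.exp(rng.normal(0, 0.05, size=2 * n))
    X = np.column_stack([num, den, rng.normal(5, 1, size=2 * n)])
    y = ["high"] * n + ["low"] * n
    return X, y


class TestFitBivariateTree:
    def test_single_class_single_leaf(self):
        tree = fit_bivariate_tree(np.arange(10.0).reshape(5, 2), ["a"] * 5, min_leaf=1)
        assert tree.root.is_leaf and tree.depth() == 0

    def test_min_leaf_n_single_majority_leaf(self):
        X = np.arange(12.0).reshape(6, 2)
        tree = fit_bivariate_tree(X, ["a", "a", "a", "a", "b", "b"], min_leaf=6)
        assert tree.root.is_leaf
        assert predict_bivariate(tree, X)[0] == "a"

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            fit_bivariate_tree(np.empty((0, 2)), [])

    def test_ratio_fixture_root_is_division_and_perfect(self, ratio_fixture):
        X, y = ratio_fixture
        tree = fit_bivariate_tree(X, y, min_leaf=1, max_depth=4)
        assert tree.root.split.op == "/"
        assert {tree.root.split.feature_i, tree.root.split.feature_j} == {0, 1}
        assert (predict_bivariate(tree, X) == np.asarray(y, object)).all()

    def test_univariate_separable_data_matches_univariate_tree(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = list(np.where(X[:, 1] > 0.2, "pos", "neg"))
        full = fit_bivariate_tree(X, y, min_leaf=1)
        uni = fit_bivariate_tree(X, y, min_leaf=1, ops=(IDENTITY,))
        acc_full = (predict_bivariate(full, X) == np.asarray(y, object)).mean()
        acc_uni = (predict_bivariate(uni, X) == np.asarray(y, object)).mean()
        assert acc_full == acc_uni == 1.0

    def test_leaf_counts_partition_cases(self, ratio_fixture):
        X, y = ratio_fixture
        tree = fit_bivariate_tree(X, y, min_leaf=3, max_depth=5)

        def leaf_total(node):
            return node.counts.sum() if node.is_leaf else leaf_total(node.left) + leaf_total(node.right)

        assert leaf_total(tree.root) == len(X)

    def test_deterministic(self, ratio_fixture):
        X, y = ratio_fixture
        a = tree_to_dict(fit_bivariate_tree(X, y, min_leaf=2))
        b = tree_to_dict(fit_bivariate_tree(X, y, min_leaf=2))
        assert a == b


class TestPredictExplain:
    def test_single_leaf_empty_path(self):
        tree = fit_bivariate_tree(np.arange(10.0).reshape(5, 2), ["a"] * 5)
        label, path = explain_bivariate(tree, np.array([1.0, 2.0]))
        assert label == "a" and path == []

    def test_explanation_names_only_path_expressions(self, ratio_fixture):
        X, y = ratio_fixture
        tree = fit_bivariate_tree(X, y, min_leaf=1, max_depth=4)
        label, path = explain_bivariate(tree, X[0])
        assert label == y[0]
        assert all(step["branch"] in ("<=", ">") for step in path)
        assert path[0]["expression"] == tree.root.split.expression(tree.feature_names)

    def test_zero_denominator_flagged_at_prediction(self, ratio_fixture):
        X, y = ratio_fixture
        tree = fit_bivariate_tree(X, y, min_leaf=1, max_depth=2)
        assert tree.root.split.op == "/"
        sample = X[0].copy()
        sample[tree.root.split.feature_j] = 0.0
        label, path = explain_bivariate(tree, sample)
        assert path[0]["guard_applied"] is True
        assert label in set(y)

    def test_serialization_roundtrip_preserves_predictions(self, ratio_fixture):
        X, y = ratio_fixture
        tree = fit_bivariate_tree(X, y, min_leaf=2)
        back = tree_from_dict(tree_to_dict(tree))
        assert (predict_bivariate(tree, X) == predict_bivariate(back, X)).all()
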