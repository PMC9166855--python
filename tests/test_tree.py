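"""CART growing/pruning and the alternating mixed-model tree."""

import numpy as np
import pytest

from emels import fit_cart, predict_tree, simulate_tree_scenario
from emels.tree import EMELSTree, _best_split


def exhaustive_best_split(X, y, minbucket):
    """Brute-force SSE search over every (variable, midpoint) candidate."""
    best = None
    n = len(y)
    for j in range(X.shape[1]):
        xs = np.unique(X[:, j])
        for a, b in zip(xs[:-1], xs[1:]):
            s = 0.5 * (a + b)
            left = X[:, j] < s
            nl = left.sum()
            if nl < minbucket or n - nl < minbucket:
                continue
            sse = (((y[left] - y[left].mean()) ** 2).sum()
                   + ((y[~left] - y[~left].mean()) ** 2).sum())
            if best is None or sse < best[0] - 1e-12:
                best = (sse, j, s)
    return best


def test_constant_response_yields_single_leaf():
    X = np.random.default_rng(0).uniform(size=(50, 3))
    tree = fit_cart(X, np.full(50, 3.5), minsplit=10, cv_folds=0)
    assert tree.n_leaves == 1
    assert tree.root.mean == pytest.approx(3.5)


def test_step_function_recovered():
    rng = np.random.default_rng(1)
    X = rng.uniform(0, 10, size=(200, 2))
    y = (X[:, 0] >= 5).astype(float) + 0.05 * rng.normal(size=200)
    tree = fit_cart(X, y, minsplit=20, cv_folds=0)
    assert tree.root.var == 0
    assert tree.root.split == pytest.approx(5.0, abs=0.5)
    preds = predict_tree(tree, np.array([[1.0, 5.0], [9.0, 5.0]]))
    assert preds[0] == pytest.approx(0.0, abs=0.1)
    assert preds[1] == pytest.approx(1.0, abs=0.1)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_split_search_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(50, 500)
    X = rng.uniform(0, 1, size=(n, 4))
    y = X[:, 0] * 2 + np.sin(5 * X[:, 1]) + rng.normal(size=n)
    got = _best_split(X, y, minbucket=6)
    ref = exhaustive_best_split(X, y, minbucket=6)
    assert got is not None and ref is not None
    assert got[1] == ref[1]
    assert got[2] == pytest.approx(ref[2], abs=1e-12)
    assert got[0] == pytest.approx(ref[0], rel=1e-10)


def test_sklearn_agrees_on_root_split():
    """Independent implementation check: sklearn's greedy SSE splitter
    picks the same root variable and an equivalent threshold."""
    from sklearn.tree import DecisionTreeRegressor
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 10, size=(300, 3))
    y = np.where(X[:, 1] > 4.2, 2.0, -1.0) + 0.2 * rng.normal(size=300)
    tree = fit_cart(X, y, minsplit=20, cv_folds=0)
    sk = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
    assert tree.root.var == sk.tree_.feature[0]
    # sklearn computes midpoints on float32 features
    assert tree.root.split == pytest.approx(sk.tree_.threshold[0], abs=1e-5)


def test_training_rows_predict_leaf_means():
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(120, 2))
    y = rng.normal(size=120)
    tree = fit_cart(X, y, minsplit=15, cv_folds=0)
    idx = tree.leaf_index(X)
    preds = tree.predict(X)
    for g, leaf in enumerate(tree.leaves()):
        rows = idx == g
        assert leaf.n == rows.sum()
        assert leaf.mean == pytest.approx(y[rows].mean())
        np.testing.assert_allclose(preds[rows], leaf.mean)


def test_routing_matches_indicator_evaluation():
    """Dummy-matrix routing equals brute-force region membership."""
    rng = np.random.default_rng(4)
    X = rng.uniform(0, 10, size=(150, 3))
    y = X[:, 0] + rng.normal(size=150)
    tree = fit_cart(X, y, minsplit=20, cv_folds=0)
    D = tree.dummy_matrix(X)
    assert np.all(D.sum(axis=1) == 1.0)       # exactly one region per row
    np.testing.assert_allclose(D @ np.array([lf.mean for lf in tree.leaves()]),
                               tree.predict(X))


def test_pruned_tree_is_smaller_subtree():
    rng = np.random.default_rng(5)
    X = rng.uniform(size=(300, 3))
    y = rng.normal(size=300)   # pure noise: pruning should cut hard
    full = fit_cart(X, y, cp=0.0005, minsplit=10, cv_folds=0)
    pruned = fit_cart(X, y, cp=0.0005, minsplit=10, cv_folds=10, seed=0)
    assert pruned.n_leaves <= full.n_leaves
    # pruned splits are a subset of the full tree's splits
    def rules(t):
        out = set()
        def rec(n):
            if not n.is_leaf:
                out.add((n.var, round(n.split, 12)))
                rec(n.left); rec(n.right)
        rec(t.root)
        return out
    assert rules(pruned) <= rules(full)


def test_minsplit_validation():
    with pytest.raises(ValueError):
        fit_cart(np.zeros((5, 1)), np.zeros(5), minsplit=1)


@pytest.fixture(scope="module")
def small_tree_scenario():
    return simulate_tree_scenario(I=40, T=15, seed=9)


def test_alternating_tree_recovers_structure(small_tree_scenario):
    """On piecewise-constant data the alternation finds the four regions
    with splits near 5 on x1/x2/x3 and effects near 10..13."""
    ds, _ = small_tree_scenario
    res = EMELSTree(ds, inner="mem",
                    cart_params={"cp": 0.001, "minsplit": 20,
                                 "cv_folds": 10, "seed": 0}).fit()
    assert res.tree.n_leaves == 4
    assert res.tree.split_variables() == {0, 1, 2}
    assert res.tree.root.split == pytest.approx(5.0, abs=0.4)
    np.testing.assert_allclose(np.sort(res.leaf_values),
                               [10, 11, 12, 13], atol=0.4)
    # once the tree structure stabilizes the refits never degrade (the
    # trace may drop earlier when a refreshed tree prunes noise splits)
    assert res.loglik_trace[-1] - res.loglik_trace[-2] > -0.1
    # population prediction routes through the mixed-model leaf effects
    row = np.array([1.0, 2.0, 7.0, 9.0] + [5.0] * 6)  # const + x1..x9
    pred = res.forecast(row, task=2).y_hat
    assert pred == pytest.approx(np.sort(res.leaf_values)[1], abs=0.4)


def test_zero_variance_effects_reduce_to_plain_cart(small_tree_scenario):
    """If random effects explain nothing, the first-step residual target
    equals y and the alternation stabilizes after one refit."""
    ds, _ = small_tree_scenario
    direct = fit_cart(
        np.vstack([s.X[:, 1:] for s in ds.series]),
        np.concatenate([s.y for s in ds.series]),
        minsplit=20, cv_folds=10, seed=0)
    res = EMELSTree(ds, inner="mem",
                    cart_params={"cp": 0.001, "minsplit": 20,
                                 "cv_folds": 10, "seed": 0}).fit(max_alt=1)
    # the first tree of the alternation is exactly the direct CART on y
    assert res.tree.to_dict() == direct.to_dict()
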