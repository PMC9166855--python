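"""CART regression trees and the alternating location-scale tree model.

The tree side is a self-contained CART implementation following the rpart
conventions the rest of the literature delegates to: greedy binary
splitting minimizing within-node SSE, candidate split points at midpoints
between consecutive distinct sorted values, a split kept only when it
improves the *relative* SSE (scaled by the root SSE) by at least ``cp``,
a minimum node size for splitting (``minsplit``) and per-leaf
(``minbucket = floor(minsplit/3)``), and weakest-link cost-complexity
pruning with the subtree chosen by K-fold cross-validation (no 1-SE rule).

The mixed-model tree alternates two steps (the RE-EM scheme): (1) given
empirical-Bayes effects b_i, grow+prune a tree on the random-effect-freed
residuals y - Z b_i against all predictors; (2) encode its leaves as dummy
regressors (one per leaf, no separate intercept) and refit the mixed model
on them, updating the parameters and the b_i.  Iterate until the marginal
log-likelihood stabilizes.  The inner model is either the extended
location-scale model or the plain AR(1) linear mixed model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import LongitudinalDataset
from .model import EMELS, MixedAR1, LocationScaleResults

__all__ = [
    "RegressionTree",
    "fit_cart",
    "predict_tree",
    "EMELSTree",
    "EMELSTreeResults",
    "fit_emels_tree",
]


@dataclass
class _Node:
    n: int
    mean: float
    sse: float
    var: int | None = None       # split variable index; None = leaf
    split: float | None = None   # rows with x[var] < split go left
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None


@dataclass
class RegressionTree:
    """A fitted binary regression tree.

    Routing convention: rows with ``x[var] < split`` go to the left child.
    Leaves are numbered in depth-first (left-first) order.
    """

    root: _Node
    feature_names: list = field(default_factory=list)

    # -- structure ---------------------------------------------------------
    def leaves(self) -> list:
        out = []

        def rec(node):
            if node.is_leaf:
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def split_variables(self) -> set:
        out = set()

        def rec(node):
            if not node.is_leaf:
                out.add(node.var)
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    # -- prediction --------------------------------------------------------
    def leaf_index(self, X: np.ndarray) -> np.ndarray:
        """Leaf number (0..G-1) for each row of X."""
        X = np.atleast_2d(np.asarray(X, float))
        idx = np.empty(X.shape[0], dtype=int)
        leaf_ids = {id(lf): g for g, lf in enumerate(self.leaves())}

        def rec(node, rows):
            if rows.size == 0:
                return
            if node.is_leaf:
                idx[rows] = leaf_ids[id(node)]
                return
            go_left = X[rows, node.var] < node.split
            rec(node.left, rows[go_left])
            rec(node.right, rows[~go_left])

        rec(self.root, np.arange(X.shape[0]))
        return idx

    def predict(self, X: np.ndarray) -> np.ndarray:
        means = np.array([lf.mean for lf in self.leaves()])
        return means[self.leaf_index(X)]

    def dummy_matrix(self, X: np.ndarray) -> np.ndarray:
        """Leaf-membership indicator matrix (n rows x G leaves)."""
        idx = self.leaf_index(X)
        D = np.zeros((idx.size, self.n_leaves))
        D[np.arange(idx.size), idx] = 1.0
        return D

    # -- serialization -----------------------------------------------------
    def to_text(self) -> str:
        lines = []

        def name(j):
            return self.feature_names[j] if self.feature_names else f"x[{j}]"

        def rec(node, indent, label):
            lines.append(
                f"{'  ' * indent}{label} n={node.n} mean={node.mean:.4f}"
                + ("" if node.is_leaf
                   else f" split: {name(node.var)} < {node.split:.4g}")
            )
            if not node.is_leaf:
                rec(node.left, indent + 1, f"{name(node.var)} < {node.split:.4g}:")
                rec(node.right, indent + 1, f"{name(node.var)} >= {node.split:.4g}:")

        rec(self.root, 0, "root")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def rec(node):
            d = {"n": int(node.n), "mean": float(node.mean)}
            if not node.is_leaf:
                d["var"] = (self.feature_names[node.var]
                            if self.feature_names else int(node.var))
                d["split"] = float(node.split)
                d["left"] = rec(node.left)
                d["right"] = rec(node.right)
            return d

        return rec(self.root)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _node_sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def _best_split(X, y, minbucket):
    """Exact best (var, split, sse_children) by exhaustive midpoint search.

    Ties resolved toward the lowest variable index, then the lowest split
    value (first maximum of the gain array over ascending split positions).
    """
    n = y.size
    best = None  # (sse_children, var, split)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cy = np.cumsum(ys)
        cy2 = np.cumsum(ys * ys)
        tot_y, tot_y2 = cy[-1], cy2[-1]
        nl = np.arange(1, n)
        valid = (xs[1:] > xs[:-1]) & (nl >= minbucket) & (n - nl >= minbucket)
        if not valid.any():
            continue
        sse_l = cy2[:-1] - cy[:-1] ** 2 / nl
        nr = n - nl
        sse_r = (tot_y2 - cy2[:-1]) - (tot_y - cy[:-1]) ** 2 / nr
        sse = np.where(valid, sse_l + sse_r, np.inf)
        i = int(np.argmin(sse))
        if np.isfinite(sse[i]) and (best is None or sse[i] < best[0] - 1e-12):
            split = 0.5 * (xs[i] + xs[i + 1])
            best = (float(sse[i]), j, split)
    return best


def _grow(X, y, rows, cp_abs, minsplit, minbucket) -> _Node:
    ysub = y[rows]
    node = _Node(n=rows.size, mean=float(ysub.mean()), sse=_node_sse(ysub))
    if rows.size < minsplit or node.sse <= 0.0:
        return node
    found = _best_split(X[rows], ysub, minbucket)
    if found is None:
        return node
    sse_children, var, split = found
    if node.sse - sse_children < cp_abs:
        return node
    go_left = X[rows, var] < split
    node.var, node.split = var, float(split)
    node.left = _grow(X, y, rows[go_left], cp_abs, minsplit, minbucket)
    node.right = _grow(X, y, rows[~go_left], cp_abs, minsplit, minbucket)
    return node


def _subtree_stats(node):
    """(subtree SSE over leaves, leaf count)."""
    if node.is_leaf:
        return node.sse, 1
    sl, nl = _subtree_stats(node.left)
    sr, nr = _subtree_stats(node.right)
    return sl + sr, nl + nr


def _prune_at(node: _Node, alpha_abs: float) -> _Node:
    """Cost-complexity prune: collapse every subtree whose weakest link is
    <= alpha_abs (bottom-up so parents see pruned children)."""
    if node.is_leaf:
        return node
    node.left = _prune_at(node.left, alpha_abs)
    node.right = _prune_at(node.right, alpha_abs)
    sse_sub, n_leaf = _subtree_stats(node)
    if n_leaf > 1 and (node.sse - sse_sub) / (n_leaf - 1) <= alpha_abs:
        node.var = node.split = None
        node.left = node.right = None
    return node


def _alpha_sequence(root: _Node) -> list:
    """Critical weakest-link alphas of the cost-complexity path."""
    import copy

    tree = copy.deepcopy(root)
    alphas = [0.0]
    while not tree.is_leaf:
        gs = []

        def rec(node):
            if node.is_leaf:
                return
            sse_sub, n_leaf = _subtree_stats(node)
            gs.append((node.sse - sse_sub) / (n_leaf - 1))
            rec(node.left)
            rec(node.right)

        rec(tree)
        g_min = min(gs)
        alphas.append(g_min)
        tree = _prune_at(tree, g_min)
    return alphas


def fit_cart(
    X: np.ndarray,
    y: np.ndarray,
    cp: float = 0.001,
    minsplit: int = 20,
    minbucket: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    feature_names=None,
    prune: bool = True,
) -> RegressionTree:
    """Grow a CART regression tree and prune it by cross-validation.

    ``cp`` is the rpart-style complexity parameter: a split must improve the
    SSE by at least ``cp * SSE(root)``.  Pruning picks the cost-complexity
    value minimizing ``cv_folds``-fold CV error over rows (seeded fold
    assignment); set ``prune=False`` or ``cv_folds=0`` to keep the full tree.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if minsplit < 2:
        raise ValueError("minsplit must be >= 2")
    if minbucket is None:
        minbucket = max(minsplit // 3, 1)
    n = y.size
    root_sse = _node_sse(y)
    cp_abs = cp * root_sse
    rows = np.arange(n)
    root = _grow(X, y, rows, cp_abs, minsplit, minbucket)
    tree = RegressionTree(root, list(feature_names) if feature_names else
                          [f"x{j+1}" for j in range(X.shape[1])])
    if not prune or cv_folds < 2 or root.is_leaf:
        return tree
    # candidate alphas: geometric means of consecutive critical values
    alphas = _alpha_sequence(root)
    cands = [0.0] + [float(np.sqrt(max(a, 1e-30) * max(b, 1e-30)))
                     for a, b in zip(alphas[1:], alphas[2:])]
    cands = sorted(set(cands + alphas[1:]))
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(n) % cv_folds)
    cv_err = np.zeros(len(cands))
    import copy

    for f in range(cv_folds):
        test = fold == f
        if test.all() or (~test).sum() < 1:
            continue
        sub = _grow(X[~test], y[~test], np.arange((~test).sum()),
                    cp_abs, minsplit, minbucket)
        for a_i, alpha in enumerate(cands):
            pruned = _prune_at(copy.deepcopy(sub), alpha)
            pred = RegressionTree(pruned).predict(X[test])
            cv_err[a_i] += float(((y[test] - pred) ** 2).sum())
    best_alpha = cands[int(np.argmin(cv_err))]
    tree.root = _prune_at(root, best_alpha)
    return tree


def predict_tree(tree: RegressionTree, X: np.ndarray) -> np.ndarray:
    return tree.predict(X)


@dataclass
class EMELSTreeResults:
    """Alternating tree fit: final tree, inner mixed-model fit on the
    leaf-dummy design, and the alternation log-likelihood trace."""

    tree: RegressionTree
    inner_results: LocationScaleResults
    loglik_trace: list
    n_alternations: int
    converged: bool
    predictor_names: list
    col_indices: list  # positions of predictor_names in the source design

    @property
    def llf(self) -> float:
        return self.inner_results.llf

    @property
    def leaf_values(self) -> np.ndarray:
        """Leaf predictions as estimated by the mixed model (one fixed
        effect per leaf dummy)."""
        return self.inner_results.beta

    def predict_fixed(self, X_pred: np.ndarray) -> np.ndarray:
        """Population-level prediction: route rows, read off leaf effects."""
        return self.leaf_values[self.tree.leaf_index(X_pred)]

    def dummy_row(self, x_pred: np.ndarray) -> np.ndarray:
        return self.tree.dummy_matrix(np.atleast_2d(x_pred))[0]

    def to_dummy_series(self, series):
        """Re-express a person's series on the leaf-dummy design (the
        series must share the training design's column layout)."""
        from .data import PersonSeries
        D = self.tree.dummy_matrix(series.X[:, self.col_indices])
        return PersonSeries(series.person_id, series.times, series.y, D,
                            series.Z)

    def forecast(self, x_future_row: np.ndarray, H: int = 1, task: int = 2,
                 series=None):
        """H-step forecast; ``x_future_row`` is a full design row of the
        source layout (intercept included), ``series`` the person's
        history for tasks 1/3.  Trees carry no forecast-error variance."""
        from .prediction import forecast as _forecast
        x = np.asarray(x_future_row, float)[self.col_indices]
        d_row = self.dummy_row(x)
        d_ser = self.to_dummy_series(series) if series is not None else None
        return _forecast(self.inner_results, d_row, H=H, task=task,
                         series=d_ser, with_variance=False)


class EMELSTree:
    """Alternating regression-tree location-scale model (RE-EM scheme).

    Parameters
    ----------
    dataset : LongitudinalDataset
    predictors : list of column names the tree may split on (defaults to
        all non-intercept predictor columns).
    inner : "emels" or "mem" -- the mixed model refit on the leaf dummies.
    cart_params : dict passed to :func:`fit_cart` (cp, minsplit, cv_folds,
        seed ...).
    """

    def __init__(self, dataset: LongitudinalDataset, predictors=None,
                 inner: str = "emels", quad_points: int = 10,
                 cart_params: dict | None = None):
        self.dataset = dataset
        self.inner = inner
        self.quad_points = quad_points
        self.cart_params = dict(cart_params or {})
        if predictors is None:
            predictors = [n for n in dataset.predictor_names if n != "const"]
        self.predictors = list(predictors)
        cols = [dataset.predictor_names.index(n) for n in self.predictors]
        self._cols = cols
        self._Xp_blocks = [s.X[:, cols] for s in dataset.series]
        self._Xp = np.vstack(self._Xp_blocks)
        self._y = np.concatenate([s.y for s in dataset.series])
        self._Zb = [s.Z for s in dataset.series]

    def _fit_inner(self, ds, start=None, se=False):
        if self.inner == "emels":
            return EMELS(ds, quad_points=self.quad_points).fit(
                start=start, se=se)
        return MixedAR1(ds).fit(se=se)

    def fit(self, tol: float = 1e-4, max_alt: int = 15) -> EMELSTreeResults:
        """Alternate tree building and mixed-model estimation.

        Stops when the inner marginal log-likelihood changes by less than
        ``tol * (|logL| + 1)`` between alternations or the tree structure
        repeats; flagged unconverged after ``max_alt`` alternations.
        """
        b_hat = [np.zeros(s.Z.shape[1]) for s in self.dataset.series]
        trace = []
        converged = False
        prev_ll = -np.inf
        prev_sig = None
        tree = inner = None
        start = None
        n_alt = 0
        for alt in range(max_alt):
            target = self._y - np.concatenate(
                [Z @ b for Z, b in zip(self._Zb, b_hat)]
            )
            tree = fit_cart(self._Xp, target, feature_names=self.predictors,
                            **self.cart_params)
            sig = json.dumps(tree.to_dict(), sort_keys=True)
            dummies = [tree.dummy_matrix(Xb) for Xb in self._Xp_blocks]
            names = [f"leaf_{g+1}" for g in range(tree.n_leaves)]
            ds_dummy = self.dataset.with_design(dummies, names)
            start_use = start if (start is not None and
                                  len(start.beta) == tree.n_leaves) else None
            inner = self._fit_inner(ds_dummy, start=start_use)
            ll = inner.llf
            trace.append(ll)
            n_alt = alt + 1
            b_hat = [inner.random_effects.v[i, : inner.k]
                     for i in range(self.dataset.n_persons)]
            if self.inner == "emels":
                from .params import Theta
                start = Theta.from_vector(inner.theta_vector,
                                          len(inner.beta), inner.k)
            if (abs(ll - prev_ll) < tol * (abs(ll) + 1.0)
                    or sig == prev_sig):
                converged = True
                break
            prev_ll, prev_sig = ll, sig
        return EMELSTreeResults(tree, inner, trace, n_alt, converged,
                                self.predictors, self._cols)


def fit_emels_tree(ds: LongitudinalDataset, k: int = 1, quad_points: int = 10,
                   cart_params=None, tol: float = 1e-4,
                   max_alt: int = 15, **kw) -> EMELSTreeResults:
    if k != 1:
        raise NotImplementedError("only the random-intercept model (k=1)")
    return EMELSTree(ds, quad_points=quad_points,
                     cart_params=cart_params, **kw).fit(tol=tol,
                                                        max_alt=max_alt)
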