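"""Bivariate binary decision tree minimizing Simpson impurity.

The second classification step differentiates bacterial infection, viral
infection and autoimmune disease/GVHD with a binary tree whose internal
nodes threshold a basic arithmetic combination of at most two features:
a raw feature, a sum, a difference, a product, or a ratio (for example
``Monocytes_abs / CD169_Mono <= 0.085``). Splits are chosen by exhaustive
search over every candidate expression and every midpoint threshold,
minimizing the case-weighted mean Simpson impurity of the two children.

Simpson impurity of a class-count vector is ``1 - sum(p_k^2)`` — the
complement of Simpson's diversity index from ecology, which measures how
evenly cases are spread over the classes. It is numerically identical to
Gini impurity; the ecological name is kept because the even-distribution
reading is the one that motivates its use here.

Tie-breaking is fully deterministic: lower weighted impurity first, then
fewer features (raw features before pairs), then lower feature indices,
then operator order (+, -, *, /), then lower threshold. Ratio candidates
are guarded: a division split is invalid at a node whenever any routed
case has |denominator| below a small epsilon, which matters because
absolute counts (e.g. eosinophils) can legitimately be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

IDENTITY = "identity"
OPS = (IDENTITY, "+", "-", "*", "/")
_OP_RANK = {"+": 0, "-": 1, "*": 2, "/": 3}
DIV_EPS = 1e-9


def simpson_impurity(counts: Sequence[float]) -> float:
    """1 - sum(p_k^2) over class proportions; 0 for a pure node."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValidationError("Simpson impurity undefined for an empty node")
    p = c / total
    return float(1.0 - (p * p).sum())


@dataclass(frozen=True)
class BivariateSplit:
    """One node test: combine feature i (and optionally j) with ``op`` and
    send cases with value <= threshold to the left child."""

    feature_i: int
    feature_j: Optional[int]
    op: str
    threshold: float

    def expression(self, names: Sequence[str]) -> str:
        if self.op == IDENTITY:
            return names[self.feature_i]
        return f"{names[self.feature_i]} {self.op} {names[self.feature_j]}"

    def describe(self, names: Sequence[str]) -> str:
        return f"{self.expression(names)} <= {self.threshold:g}"


def _candidate_list(p: int, ops: Sequence[str] = OPS) -> list[tuple[int, Optional[int], str]]:
    """All candidate (i, j, op) triples in deterministic tie-break order:
    raw features first, then pairs sorted by (i, j, op rank). + and * are
    commutative and searched once with i < j; - and / in both orders."""
    cands: list[tuple[int, Optional[int], str]] = []
    if IDENTITY in ops:
        cands.extend((i, None, IDENTITY) for i in range(p))
    pair_cands = []
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            for op in ops:
                if op == IDENTITY:
                    continue
                if op in "+*" and i > j:
                    continue
                pair_cands.append((i, j, op))
    pair_cands.sort(key=lambda t: (t[0], t[1], _OP_RANK[t[2]]))
    cands.extend(pair_cands)
    return cands


def _transform_columns(X: np.ndarray, cands, eps: float = DIV_EPS) -> np.ndarray:
    """(n, T) matrix of candidate expression values; guarded divisions are
    NaN wherever |denominator| < eps."""
    n = len(X)
    V = np.empty((n, len(cands)))
    for t, (i, j, op) in enumerate(cands):
        if op == IDENTITY:
            V[:, t] = X[:, i]
        elif op == "+":
            V[:, t] = X[:, i] + X[:, j]
        elif op == "-":
            V[:, t] = X[:, i] - X[:, j]
        elif op == "*":
            V[:, t] = X[:, i] * X[:, j]
        else:
            den = X[:, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                V[:, t] = np.where(np.abs(den) < eps, np.nan, X[:, i] / den)
    return V


def _search_best(V: np.ndarray, codes: np.ndarray, K: int, min_leaf: int):
    """Vectorized scan over all columns of V and all midpoint thresholds.

    Returns (col, threshold, weighted_impurity) or None. Within equal
    impurity the lowest column index wins, then the lowest threshold —
    columns are already in canonical candidate order and thresholds
    ascend with sort position.
    """
    m, T = V.shape
    if m < 2 * min_leaf:
        return None
    order = np.argsort(V, axis=0, kind="stable")
    sv = np.take_along_axis(V, order, axis=0)
    onehot = np.zeros((m, K))
    onehot[np.arange(m), codes] = 1.0
    cum = np.cumsum(onehot[order], axis=0)  # (m, T, K)
    totals = onehot.sum(axis=0)  # (K,)

    left_n = np.arange(1, m + 1, dtype=float)[:, None]
    right_n = m - left_n
    sumsq_left = (cum**2).sum(axis=2)
    sumsq_right = ((totals[None, None, :] - cum) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        weighted = (left_n - sumsq_left / left_n + right_n - sumsq_right / right_n) / m

    valid = np.zeros((m, T), dtype=bool)
    valid[:-1] = sv[1:] > sv[:-1]  # only between distinct consecutive values
    valid &= (left_n >= min_leaf) & (right_n >= min_leaf)
    valid &= ~np.isnan(V).any(axis=0)[None, :]  # division guard is per node
    valid[-1] = False
    if not valid.any():
        return None
    weighted = np.where(valid, weighted, np.inf)

    wmin = weighted.min()
    tied = np.argwhere(weighted <= wmin + 1e-12)
    # tie order: candidate column first, then threshold (= sort position)
    s, t = min(tied, key=lambda st: (st[1], st[0]))
    thr = float((sv[s, t] + sv[s + 1, t]) / 2.0)
    return int(t), thr, float(weighted[s, t])


def best_bivariate_split(
    X,
    y: Sequence[str],
    min_leaf: int = 1,
    ops: Sequence[str] = OPS,
    eps: float = DIV_EPS,
) -> Optional[BivariateSplit]:
    """Exhaustive best split of one node; None when no admissible split
    strictly reduces the weighted Simpson impurity."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=object)
    classes = tuple(sorted(set(y)))
    codes = np.array([classes.index(v) for v in y])
    if len(classes) < 2:
        return None
    cands = _candidate_list(X.shape[1], ops)
    V = _transform_columns(X, cands, eps)
    found = _search_best(V, codes, len(classes), min_leaf)
    if found is None:
        return None
    t, thr, w = found
    parent = simpson_impurity(np.bincount(codes, minlength=len(classes)))
    if w >= parent - 1e-12:
        return None
    i, j, op = cands[t]
    return BivariateSplit(feature_i=i, feature_j=j, op=op, threshold=thr)


@dataclass
class BivNode:
    counts: np.ndarray
    split: Optional[BivariateSplit] = None
    left: Optional["BivNode"] = None
    right: Optional["BivNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def majority(self) -> int:
        return int(np.argmax(self.counts))


@dataclass
class BivariateTree:
    root: BivNode
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def n_leaves(self) -> int:
        def c(node):
            return 1 if node.is_leaf else c(node.left) + c(node.right)

        return c(self.root)


def _split_value(split: BivariateSplit, X: np.ndarray, eps: float = DIV_EPS):
    """Evaluate a node expression on rows; returns (values, guard mask).

    At prediction time a zero-guarded denominator is substituted by
    +/- eps so the case can still be routed; the guard mask flags it.
    """
    i, j, op = split.feature_i, split.feature_j, split.op
    if op == IDENTITY:
        return X[:, i], np.zeros(len(X), dtype=bool)
    a, b = X[:, i], X[:, j]
    if op == "+":
        return a + b, np.zeros(len(X), dtype=bool)
    if op == "-":
        return a - b, np.zeros(len(X), dtype=bool)
    if op == "*":
        return a * b, np.zeros(len(X), dtype=bool)
    guard = np.abs(b) < eps
    safe = np.where(guard, np.where(b >= 0, eps, -eps), b)
    return a / safe, guard


def fit_bivariate_tree(
    X,
    y: Sequence[str],
    feature_names: Optional[Sequence[str]] = None,
    min_leaf: int = 5,
    max_depth: Optional[int] = 6,
    ops: Sequence[str] = OPS,
    eps: float = DIV_EPS,
) -> BivariateTree:
    """Grow the tree recursively until nodes are pure, too small, at the
    depth cap, or no split strictly reduces impurity. Deterministic."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValidationError("empty or malformed training table")
    y = np.asarray(list(y), dtype=object)
    if len(y) != len(X):
        raise ValidationError("label length mismatch")
    classes = tuple(sorted(set(y)))
    codes = np.array([classes.index(v) for v in y])
    K = len(classes)
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(X.shape[1]))

    cands = _candidate_list(X.shape[1], ops)
    Vfull = _transform_columns(X, cands, eps)

    def grow(rows: np.ndarray, depth: int) -> BivNode:
        counts = np.bincount(codes[rows], minlength=K).astype(float)
        node = BivNode(counts=counts)
        if (counts > 0).sum() <= 1 or len(rows) < 2 * min_leaf:
            return node
        if max_depth is not None and depth >= max_depth:
            return node
        found = _search_best(Vfull[rows], codes[rows], K, min_leaf)
        if found is None:
            return node
        t, thr, w = found
        if w >= simpson_impurity(counts) - 1e-12:
            return node
        i, j, op = cands[t]
        split = BivariateSplit(i, j, op, thr)
        vals, _ = _split_value(split, X[rows], eps)
        go_left = vals <= thr
        node.split = split
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return node

    root = grow(np.arange(len(X)), 0)
    return BivariateTree(
        root=root,
        classes=classes,
        feature_names=tuple(feature_names),
        params={"min_leaf": min_leaf, "max_depth": max_depth, "ops": list(ops), "eps": eps},
    )


def predict_bivariate(tree: BivariateTree, X) -> np.ndarray:
    """Vectorized prediction of class labels."""
    if isinstance(X, pd.DataFrame):
        X = X.loc[:, list(tree.feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    eps = tree.params.get("eps", DIV_EPS)
    out = np.empty(len(X), dtype=object)

    def route(node: BivNode, rows: np.ndarray) -> None:
        if len(rows) == 0:
            return
        if node.is_leaf:
            out[rows] = tree.classes[node.majority]
            return
        vals, _ = _split_value(node.split, X[rows], eps)
        go_left = vals <= node.split.threshold
        route(node.left, rows[go_left])
        route(node.right, rows[~go_left])

    route(tree.root, np.arange(len(X)))
    return out


def explain_bivariate(tree: BivariateTree, sample) -> tuple[str, list[dict]]:
    """Route one sample and report the ordered decision path.

    Each path entry holds the expression string, its evaluated value, the
    threshold, the branch taken, and whether the division guard had to be
    applied (zero denominator substituted by epsilon).
    """
    if isinstance(sample, pd.Series):
        x = sample.loc[list(tree.feature_names)].to_numpy(dtype=float)[None, :]
    elif isinstance(sample, dict):
        x = np.array([[sample[f] for f in tree.feature_names]], dtype=float)
    else:
        x = np.asarray(sample, dtype=float)[None, :]
    eps = tree.params.get("eps", DIV_EPS)
    path: list[dict] = []
    node = tree.root
    while not node.is_leaf:
        vals, guard = _split_value(node.split, x, eps)
        left = bool(vals[0] <= node.split.threshold)
        path.append(
            {
                "expression": node.split.expression(tree.feature_names),
                "value": float(vals[0]),
                "threshold": node.split.threshold,
                "branch": "<=" if left else ">",
                "guard_applied": bool(guard[0]),
            }
        )
        node = node.left if left else node.right
    return tree.classes[node.majority], path


# -- JSON serialization -----------------------------------------------------


def tree_to_dict(tree: BivariateTree) -> dict:
    def node_doc(node: BivNode) -> dict:
        doc = {"counts": [float(c) for c in node.counts]}
        if not node.is_leaf:
            s = node.split
            doc["split"] = {
                "feature_i": s.feature_i,
                "feature_j": s.feature_j,
                "op": s.op,
                "threshold": s.threshold,
                "expression": s.describe(tree.feature_names),
            }
            doc["left"] = node_doc(node.left)
            doc["right"] = node_doc(node.right)
        else:
            doc["label"] = tree.classes[node.majority]
        return doc

    return {
        "classes": list(tree.classes),
        "feature_names": list(tree.feature_names),
        "params": tree.params,
        "root": node_doc(tree.root),
    }


def tree_from_dict(doc: dict) -> BivariateTree:
    def build(nd: dict) -> BivNode:
        node = BivNode(counts=np.asarray(nd["counts"], dtype=float))
        if "split" in nd:
            s = nd["split"]
            node.split = BivariateSplit(
                feature_i=int(s["feature_i"]),
                feature_j=None if s["feature_j"] is None else int(s["feature_j"]),
                op=s["op"],
                threshold=float(s["threshold"]),
            )
            node.left = build(nd["left"])
            node.right = build(nd["right"])
        return node

    return BivariateTree(
        root=build(doc["root"]),
        classes=tuple(doc["classes"]),
        feature_names=tuple(doc["feature_names"]),
        params=dict(doc.get("params", {})),
    )
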