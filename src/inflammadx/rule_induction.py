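"""Gain-ratio decision-tree induction and rule extraction.

This is the C4.5/C5.0-family pathway used by the first classification step:
a tree grown on binary numeric splits chosen by gain ratio (information
gain divided by split information, with the classic mean-gain guard against
denominator artifacts), converted to a ruleset of root-to-leaf conjunctions
that are then greedily simplified. Each rule carries its training coverage
and correct-case counts, which downstream ABC pruning consumes as the rule
importance measure.

Deliberately not replicated from the commercial lineage: pessimistic
error-based pruning, winnowing and boosting. The pipeline here needs only
tree -> rules -> coverage counts, and those extras would change none of the
published interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

LEQ = "<="
GT = ">"


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def split_gain_ratio(labels_parent: Sequence[float], labels_children: Sequence[Sequence[float]]) -> float:
    """Gain ratio of a candidate split, from parent and child class counts.

    Requires at least two non-empty children that exactly partition the
    parent counts. Returns 0 for an uninformative split (zero gain).
    """
    parent = np.asarray(labels_parent, dtype=float)
    children = [np.asarray(c, dtype=float) for c in labels_children]
    if any(c.shape != parent.shape for c in children):
        raise ValidationError("child count vectors must match parent shape")
    if not np.allclose(sum(children), parent):
        raise ValidationError("children do not partition the parent counts")
    sizes = np.array([c.sum() for c in children])
    if (sizes > 0).sum() < 2:
        raise ValidationError("split needs at least two non-empty children")
    n = parent.sum()
    gain = _entropy(parent) - sum(s / n * _entropy(c) for s, c in zip(sizes, children))
    if gain <= 0:
        return 0.0
    split_info = _entropy(sizes)
    return gain / split_info


@dataclass
class TreeNode:
    counts: np.ndarray  # class counts of training cases routed here
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def majority(self) -> int:
        return int(np.argmax(self.counts))


@dataclass
class DecisionTreeK:
    """Binary-split decision tree over numeric features (k-ary in classes)."""

    root: TreeNode
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=int)
        idx = np.arange(len(X))

        def route(node: TreeNode, rows: np.ndarray) -> None:
            if len(rows) == 0:
                return
            if node.is_leaf:
                out[rows] = node.majority
                return
            go_left = X[rows, node.feature] <= node.threshold
            route(node.left, rows[go_left])
            route(node.right, rows[~go_left])

        route(self.root, idx)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        codes = self.predict_codes(X)
        return np.asarray(self.classes, dtype=object)[codes]


def _best_split(X: np.ndarray, y: np.ndarray, K: int, min_leaf: int):
    """Best (feature, threshold) by gain ratio with the C4.5 mean-gain guard.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values. Candidates whose information gain falls below the mean gain of
    all positive-gain candidates are excluded before the ratio is taken.
    Ties break on lowest feature index, then lowest threshold.
    """
    n, p = X.shape
    parent_counts = np.bincount(y, minlength=K).astype(float)
    parent_entropy = _entropy(parent_counts)
    candidates = []  # (gain, ratio, feature, threshold)
    for f in range(p):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        onehot = np.zeros((n, K))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        boundary = np.flatnonzero(xs[1:] > xs[:-1])  # split after position b
        for b in boundary:
            left = cum[b]
            ln = b + 1
            rn = n - ln
            if ln < min_leaf or rn < min_leaf:
                continue
            right = parent_counts - left
            gain = parent_entropy - (ln * _entropy(left) + rn * _entropy(right)) / n
            if gain <= 1e-12:
                continue
            split_info = _entropy(np.array([ln, rn], dtype=float))
            thr = (xs[b] + xs[b + 1]) / 2.0
            candidates.append((gain, gain / split_info, f, thr))
    if not candidates:
        return None
    mean_gain = sum(c[0] for c in candidates) / len(candidates)
    eligible = [c for c in candidates if c[0] >= mean_gain - 1e-12]
    # max ratio; ties -> lowest feature index, lowest threshold
    best = min(eligible, key=lambda c: (-c[1], c[2], c[3]))
    return best[2], best[3]


def fit_tree(
    X,
    y: Sequence[str],
    feature_names: Optional[Sequence[str]] = None,
    min_leaf: int = 1,
    max_depth: Optional[int] = None,
) -> DecisionTreeK:
    """Grow a gain-ratio tree. Deterministic given inputs and parameters."""
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

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(codes[rows], minlength=K).astype(float)
        node = TreeNode(counts=counts)
        if (counts > 0).sum() <= 1:
            return node
        if len(rows) < 2 * min_leaf:
            return node
        if max_depth is not None and depth >= max_depth:
            return node
        found = _best_split(X[rows], codes[rows], K, min_leaf)
        if found is None:
            return node
        f, thr = found
        go_left = X[rows, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return node

    root = grow(np.arange(len(X)), 0)
    return DecisionTreeK(root=root, classes=classes, feature_names=tuple(feature_names))


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def holds(self, X: pd.DataFrame | np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            col = X[self.feature].to_numpy(dtype=float)
        else:
            col = np.asarray(X, dtype=float)[:, list(feature_names).index(self.feature)]
        return col <= self.threshold if self.op == LEQ else col > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass
class Rule:
    """Conjunctive rule with training coverage bookkeeping."""

    conditions: tuple[Condition, ...]
    predicted_class: str
    coverage: int = 0
    correct: int = 0

    def matches(self, X, feature_names: Sequence[str]) -> np.ndarray:
        if not self.conditions:
            return np.ones(len(X), dtype=bool)
        m = np.ones(len(X), dtype=bool)
        for cond in self.conditions:
            m &= cond.holds(X, feature_names)
        return m

    @property
    def precision(self) -> float:
        return self.correct / self.coverage if self.coverage else 0.0

    def describe(self) -> str:
        conds = " AND ".join(str(c) for c in self.conditions) or "TRUE"
        return f"IF {conds} THEN {self.predicted_class} [{self.correct}/{self.coverage}]"


@dataclass
class RuleSet:
    rules: list[Rule]
    default_class: str
    feature_names: tuple[str, ...]
    classes: tuple[str, ...] = ()


def _merge_conditions(conds: list[Condition]) -> tuple[Condition, ...]:
    """Collapse redundant thresholds per (feature, operator): keep the
    tightest bound (min for <=, max for >)."""
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for c in conds:
        key = (c.feature, c.op)
        if key not in best:
            best[key] = c.threshold
            order.append(key)
        elif c.op == LEQ:
            best[key] = min(best[key], c.threshold)
        else:
            best[key] = max(best[key], c.threshold)
    return tuple(Condition(f, op, best[(f, op)]) for f, op in order)


def _rule_counts(conds: Sequence[Condition], X, y: np.ndarray, feature_names, predicted: str) -> tuple[int, int]:
    r = Rule(tuple(conds), predicted)
    m = r.matches(X, feature_names)
    return int(m.sum()), int((y[m] == predicted).sum())


def extract_rules(tree: DecisionTreeK, X, y: Sequence[str]) -> RuleSet:
    """Convert a fitted tree to a simplified ruleset.

    One rule per leaf (the root-to-leaf conjunction), followed by greedy
    condition dropping: a condition is removed whenever removal does not
    reduce the rule's precision on the training table. Coverage and correct
    counts are recomputed after simplification. A single-leaf tree yields an
    empty ruleset whose default class is the training majority.
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    y = np.asarray(list(y), dtype=object)
    names = tree.feature_names
    default_class = tree.classes[tree.root.majority]

    paths: list[tuple[list[Condition], str]] = []

    def walk(node: TreeNode, conds: list[Condition]) -> None:
        if node.is_leaf:
            paths.append((list(conds), tree.classes[node.majority]))
            return
        fname = names[node.feature]
        walk(node.left, conds + [Condition(fname, LEQ, node.threshold)])
        walk(node.right, conds + [Condition(fname, GT, node.threshold)])

    walk(tree.root, [])

    rules: list[Rule] = []
    for conds, predicted in paths:
        conds = list(_merge_conditions(conds))
        if not conds:  # single-leaf tree
            continue
        cov, cor = _rule_counts(conds, X, y, names, predicted)
        improved = True
        while improved and len(conds) > 1:
            improved = False
            precision = cor / cov if cov else 0.0
            for i in range(len(conds)):
                trial = conds[:i] + conds[i + 1 :]
                tcov, tcor = _rule_counts(trial, X, y, names, predicted)
                if tcov > 0 and tcor / tcov >= precision - 1e-12:
                    conds, cov, cor = trial, tcov, tcor
                    improved = True
                    break
        rules.append(Rule(tuple(conds), predicted, coverage=cov, correct=cor))

    return RuleSet(rules=rules, default_class=default_class, feature_names=tuple(names), classes=tree.classes)


# -- JSON serialization -----------------------------------------------------


def ruleset_to_dict(rs: RuleSet) -> dict:
    return {
        "default_class": rs.default_class,
        "feature_names": list(rs.feature_names),
        "classes": list(rs.classes),
        "rules": [
            {
                "conditions": [
                    {"feature": c.feature, "op": c.op, "threshold": c.threshold} for c in r.conditions
                ],
                "predicted_class": r.predicted_class,
                "coverage": r.coverage,
                "correct": r.correct,
            }
            for r in rs.rules
        ],
    }


def ruleset_from_dict(doc: dict) -> RuleSet:
    rules = [
        Rule(
            tuple(Condition(c["feature"], c["op"], float(c["threshold"])) for c in r["conditions"]),
            r["predicted_class"],
            coverage=int(r["coverage"]),
            correct=int(r["correct"]),
        )
        for r in doc["rules"]
    ]
    return RuleSet(
        rules=rules,
        default_class=doc["default_class"],
        feature_names=tuple(doc["feature_names"]),
        classes=tuple(doc.get("classes", ())),
    )
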