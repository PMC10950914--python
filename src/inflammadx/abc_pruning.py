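"""Computed ABC analysis and first-step rule selection.

ABC analysis partitions a vector of positive values into three disjoint
sets along the cumulative-share curve (a Lorenz-like curve of yield versus
effort after sorting in descending order): set A holds the "important few"
largest values, set B the break-even values whose yield roughly equals the
effort of acquiring them, and set C the "trivial many" smallest values.

The operationalization here is parameter-free and works directly on the
empirical step curve:

* the A|B boundary is the curve point closest (Euclidean) to the ideal
  point (0, 1), additionally capped at the first break-even position so
  that a flat (uniform) vector yields an empty A set;
* the B|C boundary is the first point at or after the A|B boundary where
  the local slope of the curve drops strictly below 1 — beyond it, each
  further item yields less than its effort.

The first classification step feeds the per-rule training coverage counts
through this analysis and keeps the A-set rules for the inflammatory class,
capped at two rules; samples that fire any selected rule are called
inflammatory, everything else falls back to control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CONTROL, INFLAMMATORY
from .exceptions import SelectionError, ValidationError
from .rule_induction import RuleSet

logger = logging.getLogger(__name__)


@dataclass
class AbcResult:
    order: np.ndarray  # original indices sorted by descending value
    curve: np.ndarray  # (n+1, 2) cumulative (effort, yield) points incl. (0,0)
    a_set: tuple[int, ...]
    b_set: tuple[int, ...]
    c_set: tuple[int, ...]
    a_boundary: int  # curve position of the A|B boundary (0..n)
    b_boundary: int  # curve position of the B|C boundary (a_boundary..n)


def abc_analysis(values: Sequence[float]) -> AbcResult:
    """Partition positive values into the A ("important few"), B
    (break-even) and C ("trivial many") sets. See module docstring for the
    boundary definitions."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("ABC analysis needs at least one value")
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValidationError("ABC analysis requires strictly positive finite values")

    n = v.size
    order = np.argsort(-v, kind="stable")
    sorted_v = v[order]
    total = sorted_v.sum()
    effort = np.arange(n + 1) / n
    yield_frac = np.concatenate([[0.0], np.cumsum(sorted_v) / total])
    curve = np.column_stack([effort, yield_frac])

    # Slope of segment i (between points i-1 and i) relative to the diagonal:
    # slope_i = value_i * n / total, i.e. item value in units of the mean.
    slopes = sorted_v * n / total

    dist = np.hypot(effort, 1.0 - yield_frac)
    closest = int(np.argmin(dist))  # smallest index on exact ties (argmin)
    # First position whose NEXT item is at or below break-even.
    at_or_below = np.flatnonzero(slopes <= 1.0 + 1e-12)
    break_even = int(at_or_below[0]) if at_or_below.size else n
    a_boundary = min(closest, break_even)

    below = np.flatnonzero(slopes < 1.0 - 1e-12)
    later = below[below >= a_boundary]
    b_boundary = int(later[0]) if later.size else n

    return AbcResult(
        order=order,
        curve=curve,
        a_set=tuple(int(i) for i in order[:a_boundary]),
        b_set=tuple(int(i) for i in order[a_boundary:b_boundary]),
        c_set=tuple(int(i) for i in order[b_boundary:]),
        a_boundary=a_boundary,
        b_boundary=b_boundary,
    )


@dataclass
class Step1Classifier:
    """First-step classifier: at most two rules for the inflammatory
    superclass, with control as the fall-through class."""

    rules: RuleSet
    positive_class: str = INFLAMMATORY
    fallback_class: str = CONTROL
    metadata: dict = field(default_factory=dict)

    def fired(self, X, feature_names=None) -> np.ndarray:
        """Boolean (n, n_rules) matrix of which rule fires on which row."""
        names = feature_names or self.rules.feature_names
        if not self.rules.rules:
            return np.zeros((len(X), 0), dtype=bool)
        return np.column_stack([r.matches(X, names) for r in self.rules.rules])

    def predict(self, X, feature_names=None) -> np.ndarray:
        any_fired = self.fired(X, feature_names).any(axis=1)
        return np.where(any_fired, self.positive_class, self.fallback_class)


RULE_IMPORTANCE = ("coverage", "correct", "precision")


def select_step1_rules(
    rules: RuleSet,
    positive_class: str = INFLAMMATORY,
    max_rules: int = 2,
    importance: str = "coverage",
) -> Step1Classifier:
    """Keep the most important positive-class rules by ABC analysis.

    Rule importance defaults to the training coverage count (the number of
    cases satisfying the rule's conditions). The A-set rules, ranked by
    descending importance, are kept and truncated to ``max_rules``; if the
    A set is smaller, it is padded from the B set.
    """
    if importance not in RULE_IMPORTANCE:
        raise ValidationError(f"importance must be one of {RULE_IMPORTANCE}")
    pos = [r for r in rules.rules if r.predicted_class == positive_class]
    if not pos:
        raise SelectionError(f"no rule predicts {positive_class!r}")
    usable = [r for r in pos if r.coverage > 0]
    if not usable:
        raise SelectionError("all positive-class rules have zero coverage")
    if len(usable) < len(pos):
        logger.warning("dropping %d zero-coverage rule(s)", len(pos) - len(usable))

    values = [
        {"coverage": r.coverage, "correct": r.correct, "precision": r.precision}[importance]
        for r in usable
    ]
    if len(usable) == 1:
        logger.warning("only one positive-class rule available; selection cannot be padded to %d", max_rules)
        selected = list(usable)
    else:
        res = abc_analysis(values)
        ranked_a = [usable[i] for i in res.a_set]
        ranked_b = [usable[i] for i in res.b_set]
        selected = (ranked_a + ranked_b)[:max_rules]
        if len(ranked_a) > max_rules:
            logger.info("ABC A set holds %d rules; truncating to %d", len(ranked_a), max_rules)

    sel = RuleSet(
        rules=list(selected),
        default_class=CONTROL,
        feature_names=rules.feature_names,
        classes=(INFLAMMATORY, CONTROL),
    )
    for r in sel.rules:
        logger.info("selected step-1 rule: %s", r.describe())
    return Step1Classifier(
        rules=sel,
        positive_class=positive_class,
        metadata={"importance": importance, "max_rules": max_rules, "n_candidate_rules": len(pos)},
    )


def apply_step1(classifier: Step1Classifier, sample) -> tuple[str, dict]:
    """Classify one sample and explain which rules fired.

    ``sample`` is a mapping/Series of feature name -> value. Returns the
    label (inflammatory superclass or control) and an explanation listing
    every fired rule with its conditions.
    """
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    names = classifier.rules.feature_names
    missing = [f for f in {c.feature for r in classifier.rules.rules for c in r.conditions} if f not in sample]
    if missing:
        raise ValidationError(f"sample lacks feature(s) {sorted(missing)}")
    row = pd.DataFrame([{k: sample[k] for k in names if k in sample}])
    fired = classifier.fired(row)
    fired_rules = [r for r, f in zip(classifier.rules.rules, fired[0]) if f]
    label = classifier.positive_class if fired_rules else classifier.fallback_class
    explanation = {
        "label": label,
        "fired_rules": [r.describe() for r in fired_rules],
        "note": "no rule fired; fallback to control" if not fired_rules else "",
    }
    return label, explanation
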