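"""Confusion matrices, report metrics and exact binomial intervals.

The per-class "sensitivity" and "specificity" conventions implemented here
are column-wise (predictive-value style): sensitivity of class c is
TP / (column total of predictions c), and specificity is TN / (everything
not predicted c), with the per-class "accuracy" being their arithmetic
mean. These are the conventions that reproduce the published per-class
report values cell for cell; they differ from the textbook row-wise
definitions, which are therefore also returned under the unambiguous
names ``recall`` (row-wise sensitivity) and ``true_negative_rate``
(row-wise specificity).

Overall accuracies carry exact Clopper-Pearson binomial confidence
intervals (Beta-quantile form), which is the interval construction that
matches the published CIs digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CLASS_LABELS, INFLAMMATORY_CLASSES
from .exceptions import MetricError, ValidationError


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding as used in printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are the true class, columns the predicted class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.labels)
        if self.counts.shape != (K, K):
            raise ValidationError(f"counts must be {K}x{K}")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown class {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    t = np.asarray(list(true_labels), dtype=object)
    p = np.asarray(list(predicted_labels), dtype=object)
    if len(t) != len(p):
        raise ValidationError("true and predicted label sequences differ in length")
    if labels is None:
        labels = [l for l in CLASS_LABELS if l in set(t) | set(p)] or sorted(set(t) | set(p))
    labels = tuple(labels)
    lut = {l: i for i, l in enumerate(labels)}
    unknown = (set(t) | set(p)) - set(labels)
    if unknown:
        raise ValidationError(f"label(s) outside the vocabulary: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(t, p):
        counts[lut[a], lut[b]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


@dataclass
class ClassMetrics:
    label: str
    # report conventions (column-wise), in percent
    accuracy_paper: float
    sensitivity_paper: float
    specificity_paper: float
    # textbook row-wise definitions, in percent
    recall: float
    true_negative_rate: float


def class_metrics(cm: ConfusionMatrix, label: str) -> ClassMetrics:
    j = cm.index_of(label)
    n = cm.n
    tp = int(cm.counts[j, j])
    col = int(cm.col_totals()[j])
    row = int(cm.row_totals()[j])
    if col == 0:
        raise MetricError(f"no case predicted as {label!r}; column metrics undefined")
    sens = 100.0 * tp / col
    fn = row - tp
    tn = n - col - fn
    if n - col == 0:
        raise MetricError(f"every case predicted as {label!r}; specificity undefined")
    spec = 100.0 * tn / (n - col)
    # row-wise textbook values
    recall = 100.0 * tp / row if row else float("nan")
    fp = col - tp
    negatives = n - row
    tnr = 100.0 * (negatives - fp) / negatives if negatives else float("nan")
    return ClassMetrics(
        label=label,
        accuracy_paper=(sens + spec) / 2.0,
        sensitivity_paper=sens,
        specificity_paper=spec,
        recall=recall,
        true_negative_rate=tnr,
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of cases on the diagonal."""
    return 100.0 * cm.trace / cm.n


def dichotomized_accuracy(cm: ConfusionMatrix, positive_set: Iterable[str]) -> float:
    """Accuracy (%) after collapsing the matrix to positive-set vs rest."""
    pos = {cm.index_of(l) for l in positive_set}
    if not pos or len(pos) == len(cm.labels):
        raise ValidationError("positive set must be a non-empty proper subset of the classes")
    correct = 0
    for i in range(len(cm.labels)):
        for j in range(len(cm.labels)):
            if (i in pos) == (j in pos):
                correct += cm.counts[i, j]
    return 100.0 * correct / cm.n


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI via Beta quantiles; returned as fractions."""
    if not 0 <= successes <= n or n <= 0:
        raise ValidationError("need 0 <= successes <= n with n > 0")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def misclassification_report(
    cm: ConfusionMatrix, superclass: Sequence[str] = INFLAMMATORY_CLASSES
) -> pd.DataFrame:
    """Off-diagonal cells with their share of the true class and of the
    superclass (e.g. nine AID/GVHD cases predicted viral are 37.5% of the
    24 AID/GVHD cases and 11.25% of the 80 inflammatory cases)."""
    rows = []
    row_totals = cm.row_totals()
    super_idx = [cm.index_of(l) for l in superclass if l in cm.labels]
    super_total = int(row_totals[super_idx].sum()) if super_idx else 0
    for i, true in enumerate(cm.labels):
        for j, pred in enumerate(cm.labels):
            if i == j or cm.counts[i, j] == 0:
                continue
            count = int(cm.counts[i, j])
            rows.append(
                {
                    "true": true,
                    "predicted": pred,
                    "count": count,
                    "pct_of_true_class": 100.0 * count / row_totals[i],
                    "pct_of_superclass": (
                        100.0 * count / super_total if true in superclass and super_total else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["true", "predicted", "count", "pct_of_true_class", "pct_of_superclass"])


def table_report(cm: ConfusionMatrix, ndigits: int = 2) -> pd.DataFrame:
    """Report table in the published shape: counts by predicted class plus
    the three per-class report metrics, rounded half-up."""
    rows = []
    for label in cm.labels:
        i = cm.index_of(label)
        try:
            m = class_metrics(cm, label)
            acc, sens, spec = (
                round_half_up(m.accuracy_paper, ndigits),
                round_half_up(m.sensitivity_paper, ndigits),
                round_half_up(m.specificity_paper, ndigits),
            )
        except MetricError:
            acc = sens = spec = np.nan
        row = {f"pred_{p}": int(cm.counts[i, cm.index_of(p)]) for p in cm.labels}
        row.update({"accuracy_pct": acc, "sensitivity_pct": sens, "specificity_pct": spec})
        rows.append(row)
    return pd.DataFrame(rows, index=list(cm.labels))


def report_markdown(cm: ConfusionMatrix, ndigits: int = 2) -> str:
    df = table_report(cm, ndigits)
    header = ["true class", *df.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [f"{v:g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
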