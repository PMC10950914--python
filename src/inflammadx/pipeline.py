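"""The end-to-end two-step explainable classifier.

Step 1 mirrors the physician's first decision — inflammatory condition or
not — with a gain-ratio tree converted to rules, pruned by ABC analysis to
at most two rules for the inflammatory superclass. Step 2 differentiates
bacterial, viral and autoimmune/GVHD with the bivariate Simpson-impurity
tree, trained on the inflammatory subset after fourfold SMOTE extension of
each diagnosis. Step 1 always trains on the original (non-augmented) data.

Cross-validation uses stratified folds (k = 30 by default). Because the
published procedure augments the data set before cross-validating — which
leaks synthetic neighbours of test cases into training folds — the default
here is leakage-safe fold-internal augmentation, with ``paper_mode=True``
replicating the augment-then-split ordering for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .abc_pruning import Step1Classifier, select_step1_rules
from .bivariate import (
    BivariateTree,
    explain_bivariate,
    fit_bivariate_tree,
    predict_bivariate,
    tree_from_dict,
    tree_to_dict,
)
from .datamodel import (
    CLASS_LABELS,
    CONTROL,
    DEFAULT_SCHEMA,
    INFLAMMATORY,
    INFLAMMATORY_CLASSES,
    CohortTable,
    FeatureSchema,
)
from .exceptions import ValidationError
from .metrics import ClassMetrics, ConfusionMatrix, class_metrics, clopper_pearson, confusion_matrix, overall_accuracy
from .rule_induction import extract_rules, fit_tree, ruleset_from_dict, ruleset_to_dict
from .smote import SmoteConfig, smote_extend

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class XaiConfig:
    """Training hyperparameters of the two-step model."""

    step1_min_leaf: int = 5
    step1_max_depth: Optional[int] = None
    step2_min_leaf: int = 5
    step2_max_depth: Optional[int] = 6
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    rule_importance: str = "coverage"
    max_rules: int = 2


@dataclass
class XaiModel:
    step1: Step1Classifier
    step2: Optional[BivariateTree]
    schema: FeatureSchema
    metadata: dict = field(default_factory=dict)

    def predict(self, features) -> np.ndarray:
        """Vectorized labels for a feature DataFrame (or CohortTable)."""
        if isinstance(features, CohortTable):
            features = features.features
        feats = features.loc[:, list(self.schema.names)]
        out = np.empty(len(feats), dtype=object)
        inflamed = self.step1.predict(feats) == INFLAMMATORY
        out[~inflamed] = CONTROL
        if inflamed.any():
            if self.step2 is None:
                out[inflamed] = self.metadata.get("step2_constant_class", INFLAMMATORY_CLASSES[0])
            else:
                out[inflamed] = predict_bivariate(self.step2, feats.loc[inflamed])
        return out

    def explain(self, sample) -> dict:
        """Per-sample explanation: fired step-1 rules plus the step-2 path."""
        if isinstance(sample, pd.DataFrame):
            sample = sample.iloc[0]
        if isinstance(sample, pd.Series):
            sample = sample.to_dict()
        from .abc_pruning import apply_step1

        label1, expl1 = apply_step1(self.step1, sample)
        result = {"step1": expl1, "step2": None, "label": CONTROL}
        if label1 == INFLAMMATORY:
            if self.step2 is None:
                result["label"] = self.metadata.get("step2_constant_class", INFLAMMATORY_CLASSES[0])
                result["step2"] = {"note": "constant second step (single inflammatory class at training)"}
            else:
                label2, path = explain_bivariate(self.step2, sample)
                result["label"] = label2
                result["step2"] = {"path": path}
        return result

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "inflammadx-model",
            "version": _pkg_version,
            "schema": list(self.schema.names),
            "step1": {
                "rules": ruleset_to_dict(self.step1.rules),
                "positive_class": self.step1.positive_class,
                "fallback_class": self.step1.fallback_class,
                "metadata": self.step1.metadata,
            },
            "step2": None if self.step2 is None else tree_to_dict(self.step2),
            "metadata": self.metadata,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, doc: dict, schema: FeatureSchema = DEFAULT_SCHEMA) -> "XaiModel":
        if list(schema.names) != list(doc["schema"]):
            raise ValidationError("model schema does not match the expected feature schema")
        s1 = doc["step1"]
        step1 = Step1Classifier(
            rules=ruleset_from_dict(s1["rules"]),
            positive_class=s1["positive_class"],
            fallback_class=s1["fallback_class"],
            metadata=dict(s1.get("metadata", {})),
        )
        step2 = None if doc["step2"] is None else tree_from_dict(doc["step2"])
        return cls(step1=step1, step2=step2, schema=schema, metadata=dict(doc.get("metadata", {})))

    @classmethod
    def load(cls, path, schema: FeatureSchema = DEFAULT_SCHEMA) -> "XaiModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), schema)


def fit_two_step(
    table: CohortTable,
    config: XaiConfig = XaiConfig(),
    seed: int = 0,
    _extended_inflammatory: Optional[CohortTable] = None,
) -> XaiModel:
    """Fit both steps on a cohort. Deterministic given (table, config, seed).

    ``_extended_inflammatory`` lets cross-validation inject a pre-augmented
    second-step training set (the published augment-before-split ordering);
    by default the inflammatory subset is SMOTE-extended here, fold-safely.
    """
    counts = table.class_counts()
    if counts[CONTROL] == 0:
        raise ValidationError("training cohort must contain control cases")
    present_inflammatory = [c for c in INFLAMMATORY_CLASSES if counts[c] > 0]
    if not present_inflammatory:
        raise ValidationError("training cohort must contain inflammatory cases")

    ss = np.random.SeedSequence(seed)
    smote_seed = int(ss.generate_state(1)[0] % (2**31))

    # Step 1: control vs inflammatory superclass, on the original data.
    feats = table.features
    binary = np.where(table.labels.isin(INFLAMMATORY_CLASSES), INFLAMMATORY, CONTROL)
    tree1 = fit_tree(
        feats.to_numpy(),
        binary,
        feature_names=table.schema.names,
        min_leaf=config.step1_min_leaf,
        max_depth=config.step1_max_depth,
    )
    rules = extract_rules(tree1, feats, binary)
    step1 = select_step1_rules(
        rules, INFLAMMATORY, max_rules=config.max_rules, importance=config.rule_importance
    )

    # Step 2: the three diagnoses, on the SMOTE-extended inflammatory subset.
    metadata = {
        "seed": seed,
        "config": {
            "step1_min_leaf": config.step1_min_leaf,
            "step1_max_depth": config.step1_max_depth,
            "step2_min_leaf": config.step2_min_leaf,
            "step2_max_depth": config.step2_max_depth,
            "smote_k": config.smote.k_neighbors,
            "smote_factor": config.smote.factor,
            "smote_standardize": config.smote.standardize,
            "smote_seed": smote_seed,
            "rule_importance": config.rule_importance,
        },
        "training_class_counts": counts,
        "smote_applied": _extended_inflammatory is None and config.smote.factor > 1,
        "version": _pkg_version,
    }

    step2: Optional[BivariateTree] = None
    if len(present_inflammatory) < 2:
        logger.warning("single inflammatory class %r; second step degenerates to a constant", present_inflammatory[0])
        metadata["step2_constant_class"] = present_inflammatory[0]
    else:
        if _extended_inflammatory is not None:
            train2 = _extended_inflammatory
        else:
            train2 = smote_extend(
                table.restrict_to(present_inflammatory),
                classes=present_inflammatory,
                config=config.smote,
                seed=smote_seed,
            )
        step2 = fit_bivariate_tree(
            train2.features.to_numpy(),
            train2.labels.to_numpy(dtype=object),
            feature_names=table.schema.names,
            min_leaf=config.step2_min_leaf,
            max_depth=config.step2_max_depth,
        )

    return XaiModel(step1=step1, step2=step2, schema=table.schema, metadata=metadata)


def predict_two_step(model: XaiModel, table: CohortTable, explain: bool = False):
    """Labels (and optionally per-sample explanations) for a cohort."""
    labels = model.predict(table.features)
    if not explain:
        return labels
    explanations = [model.explain(row) for _, row in table.features.iterrows()]
    return labels, explanations


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(labels: Sequence[str], k: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified fold assignment.

    Each class's members are shuffled and dealt round-robin over the k
    folds with a fold cursor carried across classes, so fold sizes differ
    by at most one even when a class is smaller than k (unavoidable with
    k = 30 and 24-member classes, where plain stratified splitters fail).
    """
    labels = np.asarray(list(labels), dtype=object)
    n = len(labels)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of cases n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    cursor = 0
    for cls in [c for c in CLASS_LABELS if c in set(labels)] or sorted(set(labels)):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        for idx in members:
            assignment[idx] = cursor % k
            cursor += 1
    return [np.flatnonzero(assignment == f) for f in range(k)]


@dataclass
class CvReport:
    k: int
    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    per_class: dict[str, Optional[ClassMetrics]]
    overall_accuracy_pct: float
    overall_ci_pct: tuple[float, float]
    mean_fold_accuracy_pct: float

    @classmethod
    def from_folds(cls, k: int, fold_pairs: list[tuple[np.ndarray, np.ndarray]], labels: Sequence[str]) -> "CvReport":
        fold_ms = [confusion_matrix(t, p, labels=labels) for t, p in fold_pairs if len(t)]
        all_true = np.concatenate([t for t, _ in fold_pairs])
        all_pred = np.concatenate([p for _, p in fold_pairs])
        pooled = confusion_matrix(all_true, all_pred, labels=labels)
        per_class: dict[str, Optional[ClassMetrics]] = {}
        for label in pooled.labels:
            try:
                per_class[label] = class_metrics(pooled, label)
            except Exception:
                per_class[label] = None
        acc = overall_accuracy(pooled)
        lo, hi = clopper_pearson(pooled.trace, pooled.n)
        fold_accs = [overall_accuracy(m) for m in fold_ms]
        return cls(
            k=k,
            fold_matrices=fold_ms,
            pooled=pooled,
            per_class=per_class,
            overall_accuracy_pct=acc,
            overall_ci_pct=(100.0 * lo, 100.0 * hi),
            mean_fold_accuracy_pct=float(np.mean(fold_accs)),
        )


def cross_validate(
    table: CohortTable,
    k: int = 30,
    config: XaiConfig = XaiConfig(),
    seed: int = 0,
    paper_mode: bool = False,
) -> CvReport:
    """k-fold cross-validation of the full two-step model.

    With ``paper_mode=False`` (default) SMOTE runs inside each training
    fold. With ``paper_mode=True`` the inflammatory subset is augmented
    once up front and every fold trains on all synthetics — replicating
    the published augment-then-split ordering, which leaks synthetic
    neighbours of test cases and is therefore optimistically biased.
    Evaluation is always on original cases only.
    """
    folds = stratified_folds(table.labels, k, seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s % (2**31)) for s in ss.generate_state(k + 1)]

    extended_all = None
    if paper_mode:
        present = [c for c in INFLAMMATORY_CLASSES if table.class_counts()[c] > 0]
        if len(present) >= 2:
            extended_all = smote_extend(
                table.restrict_to(present), classes=present, config=config.smote, seed=fold_seeds[k]
            )

    labels_arr = table.labels.to_numpy(dtype=object)
    present_labels = [c for c in CLASS_LABELS if c in set(labels_arr)]
    fold_pairs = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(table.n), test_idx)
        train = table.subset(table.ids[train_idx])
        test = table.subset(table.ids[test_idx])
        if paper_mode and extended_all is not None:
            # train originals plus every synthetic case (leaky on purpose)
            from .smote import is_synthetic

            syn_mask = is_synthetic(extended_all.ids)
            keep = extended_all.ids[syn_mask].tolist()
            ext_feats = pd.concat([train.features, extended_all.features.loc[keep]])
            ext_labels = pd.concat([train.labels, extended_all.labels.loc[keep]])
            ext = CohortTable(
                ext_feats[ext_labels.isin(INFLAMMATORY_CLASSES)],
                ext_labels[ext_labels.isin(INFLAMMATORY_CLASSES)],
                table.schema,
            )
            model = fit_two_step(train, config, seed=fold_seeds[f], _extended_inflammatory=ext)
        else:
            model = fit_two_step(train, config, seed=fold_seeds[f])
        pred = model.predict(test.features)
        fold_pairs.append((test.labels.to_numpy(dtype=object), pred))

    return CvReport.from_folds(k, fold_pairs, labels=present_labels)


def run_baselines(
    table: CohortTable,
    k: int = 30,
    seed: int = 0,
    augment: bool = False,
    knn_neighbors: int = 5,
) -> dict[str, CvReport]:
    """k-NN and Gaussian naive-Bayes reference classifiers under the same
    fold assignment as the two-step model (features z-scored per training
    fold for k-NN). ``augment=True`` applies fold-internal SMOTE to the
    inflammatory classes before training, mirroring the second-step recipe."""
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier

    folds = stratified_folds(table.labels, k, seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s % (2**31)) for s in ss.generate_state(k)]
    labels_arr = table.labels.to_numpy(dtype=object)
    present_labels = [c for c in CLASS_LABELS if c in set(labels_arr)]

    reports: dict[str, CvReport] = {}
    for name in ("knn", "bayes"):
        fold_pairs = []
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(table.n), test_idx)
            train = table.subset(table.ids[train_idx])
            test = table.subset(table.ids[test_idx])
            if augment:
                present = [c for c in INFLAMMATORY_CLASSES if train.class_counts()[c] > 1]
                train = smote_extend(train, classes=present, seed=fold_seeds[f])
            Xtr, ytr = train.features.to_numpy(), train.labels.to_numpy(dtype=object)
            Xte = test.features.to_numpy()
            if name == "knn":
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = KNeighborsClassifier(n_neighbors=min(knn_neighbors, len(Xtr)))
                clf.fit((Xtr - mu) / sd, ytr)
                pred = clf.predict((Xte - mu) / sd)
            else:
                clf = GaussianNB()
                clf.fit(Xtr, ytr)
                pred = clf.predict(Xte)
            fold_pairs.append((test.labels.to_numpy(dtype=object), np.asarray(pred, dtype=object)))
        reports[name] = CvReport.from_folds(k, fold_pairs, labels=present_labels)
    return reports
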