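"""Feature schema, cohort container and CSV ingestion.

The universal input of the package is a cohort table: one row per patient,
18 named numeric blood parameters (CRP, 11 hemogram values, and the
relative MFI of CD169 / HLA-DR / CD64 on monocytes and neutrophils) plus a
four-level diagnosis label. The schema is shipped as a machine-readable
YAML resource so laboratory pipelines can validate exports against it.

Missing values are rejected, never imputed: silently filling cells would
change rule induction downstream, so ingestion fails loudly with the row
identifier of the offending cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .exceptions import LabelError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

# Closed label vocabulary. The three disease labels form the "inflammatory"
# superclass used by the first classification step.
BACTERIAL = "bacterial"
VIRAL = "viral"
AID_GVHD = "aid_gvhd"
CONTROL = "control"
CLASS_LABELS: tuple[str, ...] = (BACTERIAL, VIRAL, AID_GVHD, CONTROL)
INFLAMMATORY_CLASSES: tuple[str, ...] = (BACTERIAL, VIRAL, AID_GVHD)
INFLAMMATORY = "inflammatory"  # binary superclass label for step 1

LABEL_COLUMN = "diagnosis"
ID_COLUMN = "id"

N_FEATURES = 18


@dataclass(frozen=True)
class FeatureDef:
    """One feature: canonical name, laboratory unit, and feature group."""

    name: str
    unit: str
    group: str  # "crp" | "hemogram" | "mfi"

    @property
    def is_percentage(self) -> bool:
        return self.unit == "%"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 18-feature schema shared by every cohort table."""

    features: tuple[FeatureDef, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != N_FEATURES:
            raise SchemaError(f"schema must define exactly {N_FEATURES} features, got {len(names)}")
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        n_mfi = sum(f.group == "mfi" for f in self.features)
        if n_mfi != 6:
            raise SchemaError(f"schema must define exactly 6 MFI features, got {n_mfi}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def percentage_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.is_percentage)

    @property
    def mfi_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.group == "mfi")

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None

    @classmethod
    def default(cls) -> "FeatureSchema":
        """Load the canonical schema from the packaged YAML resource."""
        text = resources.files("inflammadx.data").joinpath("feature_schema.yaml").read_text()
        doc = yaml.safe_load(text)
        feats = tuple(FeatureDef(d["name"], d["unit"], d["group"]) for d in doc["features"])
        return cls(features=feats)


DEFAULT_SCHEMA = FeatureSchema.default()


@dataclass
class CohortTable:
    """n patients x 18 features plus a diagnosis label per patient.

    ``features`` is a DataFrame whose columns follow the schema order and
    whose index holds unique patient identifiers; ``labels`` is an aligned
    Series over the closed vocabulary.
    """

    features: pd.DataFrame
    labels: pd.Series
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        self.features = self.features.loc[:, list(self.schema.names)].astype(float)
        self.labels = self.labels.reindex(self.features.index)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.features) < 1:
            raise ValidationError("cohort must contain at least one patient")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValidationError(f"duplicate patient id {dup!r}")
        values = self.features.to_numpy()
        if not np.isfinite(values).all():
            bad = self.features.index[~np.isfinite(values).all(axis=1)][0]
            raise ValidationError(f"non-finite feature value in row {bad!r}")
        if (values < 0).any():
            bad = self.features.index[(values < 0).any(axis=1)][0]
            raise ValidationError(f"negative feature value in row {bad!r}")
        pct = self.features.loc[:, list(self.schema.percentage_names)].to_numpy()
        if (pct > 100).any():
            raise ValidationError("percentage feature above 100%")
        unknown = set(self.labels.unique()) - set(CLASS_LABELS)
        if unknown:
            raise LabelError(f"unknown diagnosis label(s): {sorted(unknown)}")

    # -- accessors ----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def ids(self) -> pd.Index:
        return self.features.index

    def class_counts(self) -> dict[str, int]:
        """Label -> count over the full vocabulary; absent labels count 0."""
        vc = self.labels.value_counts()
        return {label: int(vc.get(label, 0)) for label in CLASS_LABELS}

    def subset(self, mask_or_ids) -> "CohortTable":
        feats = self.features.loc[mask_or_ids]
        return CohortTable(feats.copy(), self.labels.loc[feats.index].copy(), self.schema)

    def restrict_to(self, labels: Iterable[str]) -> "CohortTable":
        keep = self.labels.isin(list(labels))
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out[LABEL_COLUMN] = self.labels
        out.index.name = ID_COLUMN
        return out

    @classmethod
    def from_arrays(
        cls,
        X,
        labels,
        ids=None,
        schema: FeatureSchema = DEFAULT_SCHEMA,
    ) -> "CohortTable":
        X = np.asarray(X, dtype=float)
        if ids is None:
            ids = [f"p{i:05d}" for i in range(len(X))]
        feats = pd.DataFrame(X, columns=list(schema.names), index=pd.Index(ids, name=ID_COLUMN))
        lab = pd.Series(list(labels), index=feats.index, name=LABEL_COLUMN)
        return cls(feats, lab, schema)


def load_cohort(path, schema: FeatureSchema = DEFAULT_SCHEMA) -> CohortTable:
    """Read and validate a cohort CSV.

    The header must name every schema feature plus the ``diagnosis`` column;
    an optional ``id`` column provides row identifiers. Extra columns are
    ignored with a logged warning. Any non-numeric, missing or out-of-range
    cell aborts ingestion with the offending row id.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in (*schema.names, LABEL_COLUMN) if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    extra = [c for c in raw.columns if c not in (*schema.names, LABEL_COLUMN, ID_COLUMN)]
    if extra:
        logger.warning("ignoring extra column(s) %s in %s", extra, path)

    if ID_COLUMN in raw.columns:
        ids = pd.Index(raw[ID_COLUMN].astype(str), name=ID_COLUMN)
    else:
        ids = pd.Index([f"row{i:05d}" for i in range(len(raw))], name=ID_COLUMN)

    feats = pd.DataFrame(index=ids)
    for name in schema.names:
        col = pd.to_numeric(raw[name], errors="coerce")
        bad = col.isna() | raw[name].isna()
        if bad.any():
            row = ids[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ValidationError(f"non-numeric or missing value for {name!r} in row {row!r}")
        feats[name] = col.to_numpy(dtype=float)

    labels = pd.Series(raw[LABEL_COLUMN].astype(str).to_numpy(), index=ids, name=LABEL_COLUMN)
    return CohortTable(feats, labels, schema)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV at full float precision (round-trips exactly)."""
    frame = table.to_frame()
    frame.to_csv(path, float_format=None)
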