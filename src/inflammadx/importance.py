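"""Permutation variable importance via the adjusted Rand index.

After the two-step model is fitted, it is applied to the (unpermuted)
cohort and the agreement between predictions and the prior diagnosis
labels is summarized by the adjusted Rand index (ARI) — that agreement is
the baseline x. Then, feature by feature, the feature's column is randomly
permuted across the rows in scope N times (default 200) without refitting
the model; each trial's prediction agreement y is turned into a relative
difference

    R = 0.5 * (x - y) / (x + y) * 100   (percent, in [-200, 200])

A feature whose R distribution sits around zero is unimportant (permuting
it did not change the predictions' agreement); a distribution above zero
marks an important feature. The per-feature R vectors can be exported with
kernel-density summaries for mirrored-density (violin-style) rendering.

The restriction ``scope="inflammatory"`` reruns the analysis on the three
inflammatory classes only, without controls — the comparison that reveals
which features matter for the second step rather than the first. The model
is reused, not refitted, on the restricted rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import INFLAMMATORY_CLASSES, CohortTable
from .exceptions import MetricError, ValidationError

logger = logging.getLogger(__name__)

R_LIMIT = 200.0


def adjusted_rand_index(partition_a: Sequence, partition_b: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index between two label sequences.

    Computed from the pair-confusion counts; 1 for identical partitions,
    approximately 0 for independent random labelings.
    """
    a = np.asarray(list(partition_a), dtype=object)
    b = np.asarray(list(partition_b), dtype=object)
    if len(a) != len(b):
        raise ValidationError("partitions differ in length")
    if len(a) < 2:
        raise ValidationError("need at least two items")
    ai = pd.factorize(a)[0]
    bi = pd.factorize(b)[0]
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    n = len(a)
    sum_sq = (contingency.astype(float) ** 2).sum()
    row = contingency.sum(axis=1).astype(float)
    col = contingency.sum(axis=0).astype(float)
    # pair counts (each pair counted twice cancels in the ratio)
    tp = sum_sq - n
    fp = (row**2).sum() - sum_sq
    fn = (col**2).sum() - sum_sq
    tn = n * n - n - tp - fp - fn
    if fp == 0 and fn == 0:
        return 1.0
    return float(2.0 * (tp * tn - fn * fp) / ((tp + fn) * (fn + tn) + (tp + fp) * (fp + tn)))


def relative_difference(x: float, y: float) -> float:
    """R = 0.5 * (x - y) / (x + y) * 100, clamped to [-200, 200].

    Undefined when x + y = 0; the caller records such trials as missing.
    """
    if x + y == 0:
        raise MetricError("relative difference undefined for x + y = 0")
    r = 0.5 * (x - y) / (x + y) * 100.0
    return float(np.clip(r, -R_LIMIT, R_LIMIT))


@dataclass(frozen=True)
class ImportanceConfig:
    n_permutations: int = 200
    scope: str = "all"  # "all" | "inflammatory"

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.scope not in ("all", "inflammatory"):
            raise ValidationError("scope must be 'all' or 'inflammatory'")


@dataclass
class ImportanceReport:
    baseline_ari: float
    r_values: pd.DataFrame  # n_permutations rows x feature columns (NaN = undefined trial)
    scope: str
    n_undefined: dict = field(default_factory=dict)

    def medians(self) -> pd.Series:
        return self.r_values.median(axis=0, skipna=True)


def permutation_importance(
    model,
    table: CohortTable,
    config: ImportanceConfig = ImportanceConfig(),
    seed: int = 0,
) -> ImportanceReport:
    """Whole-column permutation importance without refitting.

    ``model`` must expose ``predict(features_df) -> label array`` over the
    cohort's feature columns (the two-step model does). Deterministic for a
    given seed: one generator drives all features in schema order.
    """
    config.validate()
    if config.scope == "inflammatory":
        table = table.restrict_to(INFLAMMATORY_CLASSES)
    feats = table.features
    prior = table.labels.to_numpy(dtype=object)

    baseline_pred = np.asarray(model.predict(feats), dtype=object)
    x = adjusted_rand_index(prior, baseline_pred)
    logger.info("baseline ARI (scope=%s): %.4f", config.scope, x)

    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    undefined: dict[str, int] = {}
    for feat in feats.columns:
        col = feats[feat].to_numpy(dtype=float)
        rs = np.full(config.n_permutations, np.nan)
        n_undef = 0
        for t in range(config.n_permutations):
            perm = rng.permutation(col)
            trial = feats.copy()
            trial[feat] = perm
            y = adjusted_rand_index(prior, np.asarray(model.predict(trial), dtype=object))
            try:
                rs[t] = relative_difference(x, y)
            except MetricError:
                n_undef += 1
        out[feat] = rs
        if n_undef:
            undefined[feat] = n_undef
            logger.warning("%s: %d undefined R trial(s) recorded as missing", feat, n_undef)
    report = ImportanceReport(
        baseline_ari=x,
        r_values=pd.DataFrame(out),
        scope=config.scope,
        n_undefined=undefined,
    )
    return report


@dataclass
class MdPlotData:
    grid: np.ndarray
    densities: pd.DataFrame  # len(grid) rows x feature columns (NaN column = degenerate)
    raw: pd.DataFrame
    degenerate: tuple[str, ...]


def export_md_plot_data(report: ImportanceReport, grid_size: int = 128) -> MdPlotData:
    """Gaussian-KDE density of each feature's R distribution on a shared
    grid, for mirrored-density (violin) rendering. Degenerate (constant)
    distributions are flagged and exported with raw values only."""
    raw = report.r_values
    if raw.empty:
        raise ValidationError("empty importance report")
    finite = raw.to_numpy()[np.isfinite(raw.to_numpy())]
    lo, hi = (finite.min(), finite.max()) if finite.size else (-1.0, 1.0)
    pad = 0.1 * max(hi - lo, 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_size)

    dens = {}
    degenerate = []
    for feat in raw.columns:
        vals = raw[feat].dropna().to_numpy()
        if vals.size < 2 or np.std(vals) == 0:
            degenerate.append(feat)
            dens[feat] = np.full(grid_size, np.nan)
            continue
        kde = stats.gaussian_kde(vals)  # Silverman-style default bandwidth
        dens[feat] = kde(grid)
    return MdPlotData(
        grid=grid,
        densities=pd.DataFrame(dens, index=grid),
        raw=raw.copy(),
        degenerate=tuple(degenerate),
    )
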