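"""Tenfold cross-validation, repeated CV and integrated-score grid search.

Folds are plain random equal-size partitions (no stratification), so every
sample is predicted exactly once per CV run; the four measurements are
computed once over the pooled out-of-fold predictions, matching a single
sum over n samples rather than a per-fold average.  Embeddings are trained
once on the full annotation corpus, outside the folds: training uses only
term co-occurrence, never type labels, so no label leakage is possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from mptype.annotation_io import LabelMatrix
from mptype.embedding import FeatureMatrix
from mptype.metrics import MetricsRecord
from mptype.multilabel import (
    BaseClassifierSpec,
    br_fit,
    br_predict,
    rakel_fit,
    rakel_predict,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridConfig:
    """One point of the hyperparameter grid."""

    dimension: int
    k: int = 6
    m_subsets: int = 10
    base: BaseClassifierSpec = field(default_factory=BaseClassifierSpec)
    scheme: str = "rakel"
    feature_scheme: str = "embedding"

    def __post_init__(self) -> None:
        if self.scheme not in ("rakel", "br"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.feature_scheme not in ("embedding", "one-hot"):
            raise ValueError(f"unknown feature scheme {self.feature_scheme!r}")


@dataclass
class CvResult:
    config: GridConfig
    record: MetricsRecord
    fold_assignment_seed: int


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Random partition of [0, n) into folds of size differing by <= 1."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), folds)


def _fit_predict(
    train_X: FeatureMatrix,
    train_y: LabelMatrix,
    test_X: FeatureMatrix,
    config: GridConfig,
    seed: int,
) -> np.ndarray:
    if config.scheme == "rakel":
        ens = rakel_fit(
            train_X, train_y,
            base=replace(config.base, seed=seed),
            k=config.k, m=config.m_subsets, seed=seed,
        )
        _, pred = rakel_predict(ens, test_X)
        return pred
    ens = br_fit(train_X, train_y, base=replace(config.base, seed=seed))
    return br_predict(ens, test_X)


def cross_validate(
    features: FeatureMatrix,
    labels: LabelMatrix,
    config: GridConfig,
    seed: int,
    folds: int = 10,
) -> CvResult:
    """One k-fold CV run: pool all out-of-fold predictions, score once."""
    if len(features) != len(labels):
        raise ValueError("features and labels must have aligned rows")
    n = len(labels)
    parts = kfold_indices(n, folds, seed)
    pooled = np.zeros_like(labels.indicators)
    predicted = np.zeros(n, dtype=bool)
    for fold_no, test_idx in enumerate(parts):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train_X = FeatureMatrix(
            [features.protein_ids[i] for i in train_idx],
            features.values[train_idx], scheme=features.scheme,
        )
        test_X = FeatureMatrix(
            [features.protein_ids[i] for i in test_idx],
            features.values[test_idx], scheme=features.scheme,
        )
        train_y = LabelMatrix(
            [labels.protein_ids[i] for i in train_idx],
            list(labels.label_names),
            labels.indicators[train_idx],
        )
        try:
            pooled[test_idx] = _fit_predict(
                train_X, train_y, test_X, config, seed
            )
        except Exception as exc:
            raise RuntimeError(f"fold {fold_no} failed: {exc}") from exc
        predicted[test_idx] = True
    assert predicted.all(), "every sample must be predicted exactly once"
    record = MetricsRecord.from_matrices(labels.indicators, pooled)
    return CvResult(config=config, record=record, fold_assignment_seed=seed)


def repeat_cv(
    features: FeatureMatrix,
    labels: LabelMatrix,
    config: GridConfig,
    repeats: int,
    base_seed: int,
    folds: int = 10,
) -> list[CvResult]:
    """Independent CV runs at seeds base_seed .. base_seed + repeats - 1."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    results = [
        cross_validate(features, labels, config, base_seed + r, folds=folds)
        for r in range(repeats)
    ]
    for metric in ("exact_match", "accuracy", "hamming_loss", "integrated_score"):
        vals = [getattr(r.record, metric) for r in results]
        logger.info(
            "repeat_cv %s: min %.4f max %.4f", metric, min(vals), max(vals)
        )
    return results


def metric_ranges(results: Sequence[CvResult]) -> dict[str, tuple[float, float]]:
    """Min/max of each measurement across repeated CV runs."""
    out = {}
    for metric in ("exact_match", "accuracy", "hamming_loss", "integrated_score"):
        vals = [getattr(r.record, metric) for r in results]
        out[metric] = (min(vals), max(vals))
    return out


def grid_search(
    features_by_dimension: Mapping[int, FeatureMatrix],
    labels: LabelMatrix,
    grid: Sequence[GridConfig],
    seed: int,
    folds: int = 10,
) -> tuple[CvResult, list[CvResult]]:
    """Evaluate every config by CV; the winner maximizes integrated score.

    Ties break toward the simpler model: fewer trees, then smaller
    dimension, then smaller k.  All results are returned for reporting.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    for config in grid:
        if config.dimension not in features_by_dimension:
            raise ValueError(
                f"no features for dimension {config.dimension}"
            )
    results = [
        cross_validate(
            features_by_dimension[c.dimension], labels, c, seed, folds=folds
        )
        for c in grid
    ]
    best = min(
        results,
        key=lambda r: (
            -r.record.integrated_score,
            r.config.base.trees,
            r.config.dimension,
            r.config.k,
        ),
    )
    return best, results
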