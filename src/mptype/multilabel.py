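"""RAKEL and Binary Relevance multilabel ensembles.

RAKEL (RAndom k-labELsets) draws m random size-k subsets of the l labels.
For each subset, every training sample's label set is restricted to the
subset and the restriction — a member of the subset's power set, possibly
empty — becomes a single categorical class, so each sample has exactly one
class and any single-label base classifier applies.  At prediction time a
label is assigned when the proportion of classifiers whose subset contains
it AND whose predicted class includes it strictly exceeds a threshold
(default 0.5).

Binary Relevance trains one independent binary classifier per label and
ignores label correlations.

The ensemble logic here is native; base classifiers plug in behind a
minimal contract — ``fit(X, y)`` with integer class codes and
``predict(X)`` returning codes — satisfied by scikit-learn estimators.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from mptype.annotation_io import LabelMatrix
from mptype.embedding import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelSubset:
    """An ordered set of k distinct label indices in [0, l)."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("label subset must be non-empty")
        if list(self.indices) != sorted(set(self.indices)):
            raise ValueError("indices must be strictly increasing")

    def __contains__(self, label: int) -> bool:
        return label in self.indices

    def __len__(self) -> int:
        return len(self.indices)


def restrict_labels(labels: frozenset[int] | set[int], subset: LabelSubset) -> frozenset[int]:
    """Restrict a sample's label set to the subset: one power-set class.

    E.g. labels {0,1,3} restricted to subset (0,1,2) is the class {0,1};
    a sample with no label in the subset maps to the empty class.
    """
    return frozenset(labels) & frozenset(subset.indices)


def sample_label_subsets(
    l: int, k: int, m: int, seed: int
) -> list[LabelSubset]:
    """Draw m random k-subsets of the l labels, deterministically.

    Sampling is without replacement from all C(l, k) subsets while that
    many exist; otherwise with replacement (logged) — the published best
    setting k = l = 6, m = 10 necessarily repeats the one 6-subset.
    """
    if not (1 <= k <= l):
        raise ValueError(f"need 1 <= k <= l, got k={k}, l={l}")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    n_total = math.comb(l, k)
    if n_total >= m:
        all_subsets = list(combinations(range(l), k))
        picked = rng.choice(n_total, size=m, replace=False)
        return [LabelSubset(all_subsets[i]) for i in picked]
    logger.warning(
        "only %d distinct %d-subsets of %d labels for m=%d; "
        "sampling with replacement",
        n_total, k, l, m,
    )
    return [
        LabelSubset(tuple(sorted(rng.choice(l, size=k, replace=False))))
        for _ in range(m)
    ]


@dataclass(frozen=True)
class BaseClassifierSpec:
    """Single-label base classifier configuration.

    ``trees`` applies to random forests; ``C``/``exponent`` to the
    polynomial-kernel SVM; ``C``/``gamma`` to the RBF-kernel SVM.
    """

    algorithm: str = "random_forest"
    trees: int = 500
    C: float = 1.0
    exponent: int = 3
    gamma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in (
            "random_forest", "svm_polynomial", "svm_rbf", "memorizing"
        ):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def make(self, seed_offset: int = 0):
        """Instantiate a fresh estimator, offsetting the seed per model."""
        seed = (self.seed + seed_offset) % (2**31)
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.trees, random_state=seed, n_jobs=1
            )
        if self.algorithm == "svm_polynomial":
            return SVC(kernel="poly", degree=self.exponent, C=self.C,
                       random_state=seed)
        if self.algorithm == "svm_rbf":
            return SVC(kernel="rbf", gamma=self.gamma, C=self.C,
                       random_state=seed)
        return MemorizingClassifier()


class MemorizingClassifier:
    """Exact-recall base classifier for verification.

    Returns the training class of any feature row seen in training and the
    most frequent training class otherwise.  Deterministic by construction;
    used to isolate the ensemble's transformation and voting logic from
    base-classifier behaviour.
    """

    def __init__(self) -> None:
        self._memory: dict[bytes, int] = {}
        self._default: int = 0

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "MemorizingClassifier":
        y = np.asarray(y)
        for row, cls in zip(np.asarray(X, dtype=np.float64), y):
            self._memory[row.tobytes()] = int(cls)
        vals, counts = np.unique(y, return_counts=True)
        self._default = int(vals[np.argmax(counts)])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array(
            [
                self._memory.get(row.tobytes(), self._default)
                for row in np.asarray(X, dtype=np.float64)
            ]
        )


class _ConstantClassifier:
    """Stands in when a subset's training classes collapse to one class."""

    def __init__(self, value: int) -> None:
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.value, dtype=np.int64)


@dataclass
class RakelEnsemble:
    subsets: list[LabelSubset]
    models: list
    class_inventories: list[list[frozenset[int]]]
    l: int
    threshold: float = 0.5
    base: BaseClassifierSpec | None = None
    n_features: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.subsets) == len(self.models) == len(self.class_inventories)):
            raise ValueError("subsets, models and inventories must align")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.subsets)


@dataclass
class BrEnsemble:
    models: list
    l: int
    base: BaseClassifierSpec | None = None
    n_features: int | None = None


def _check_dimension(expected: int | None, X: np.ndarray) -> None:
    if expected is not None and X.shape[1] != expected:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match "
            f"training dimension {expected}"
        )


def rakel_fit(
    features: FeatureMatrix,
    labels: LabelMatrix,
    base: BaseClassifierSpec,
    k: int,
    m: int,
    seed: int,
    threshold: float = 0.5,
) -> RakelEnsemble:
    """Train a RAKEL ensemble: m power-set classifiers on random k-subsets.

    For each subset every training sample gets exactly one power-set class;
    a base classifier (seeded ``base.seed + model index`` so duplicate
    subsets stay decorrelated) is fit per subset.  A subset whose training
    classes collapse to a single class yields a constant predictor (logged).
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have aligned rows")
    X = features.values
    sets = labels.label_sets()
    subsets = sample_label_subsets(labels.n_labels, k, m, seed)
    models, inventories = [], []
    for i, subset in enumerate(subsets):
        classes = [restrict_labels(s, subset) for s in sets]
        # canonical code order (by size, then members) so base-classifier
        # tie-breaks are independent of sample order and match the binary
        # encoding used by Binary Relevance in the k=1 reduction
        inventory = sorted(set(classes), key=lambda c: (len(c), sorted(c)))
        code_of = {cls: i for i, cls in enumerate(inventory)}
        y = np.array([code_of[cls] for cls in classes], dtype=np.int64)
        if len(inventory) == 1:
            logger.warning(
                "subset %s: single training class %s; constant predictor",
                subset.indices, set(inventory[0]),
            )
            model = _ConstantClassifier(0)
        else:
            model = base.make(seed_offset=i).fit(X, y)
        models.append(model)
        inventories.append(inventory)
    return RakelEnsemble(
        subsets=subsets,
        models=models,
        class_inventories=inventories,
        l=labels.n_labels,
        threshold=threshold,
        base=base,
        n_features=X.shape[1],
    )


def rakel_predict(
    ensemble: RakelEnsemble, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Vote proportions (n x l) and thresholded binary predictions.

    For label j, the proportion is (# models whose subset contains j and
    whose predicted class includes j) / (# models whose subset contains j);
    labels covered by no subset get proportion 0.  A label is predicted iff
    its proportion STRICTLY exceeds the threshold, so exactly 0.5 at the
    default threshold is a negative.
    """
    X = features.values
    _check_dimension(ensemble.n_features, X)
    n, l = X.shape[0], ensemble.l
    votes = np.zeros((n, l))
    coverage = np.zeros(l)
    for subset, model, inventory in zip(
        ensemble.subsets, ensemble.models, ensemble.class_inventories
    ):
        for j in subset.indices:
            coverage[j] += 1
        codes = np.asarray(model.predict(X), dtype=np.int64)
        for j in subset.indices:
            includes_j = np.array(
                [j in inventory[c] for c in range(len(inventory))], dtype=bool
            )
            votes[:, j] += includes_j[codes]
    proportions = np.divide(
        votes, coverage, out=np.zeros_like(votes), where=coverage > 0
    )
    predictions = (proportions > ensemble.threshold).astype(np.int8)
    uncovered = int((coverage == 0).sum())
    if uncovered:
        logger.warning("%d labels covered by no subset", uncovered)
    n_empty = int((predictions.sum(axis=1) == 0).sum())
    if n_empty:
        logger.info("%d samples received empty predicted label sets", n_empty)
    return proportions, predictions


def br_fit(
    features: FeatureMatrix, labels: LabelMatrix, base: BaseClassifierSpec
) -> BrEnsemble:
    """One independent binary classifier per label column."""
    if len(features) != len(labels):
        raise ValueError("features and labels must have aligned rows")
    X = features.values
    models = []
    for j in range(labels.n_labels):
        y = labels.indicators[:, j].astype(np.int64)
        if len(np.unique(y)) == 1:
            logger.warning(
                "label %r has a single training class; constant predictor",
                labels.label_names[j],
            )
            models.append(_ConstantClassifier(int(y[0])))
        else:
            models.append(base.make(seed_offset=j).fit(X, y))
    return BrEnsemble(
        models=models, l=labels.n_labels, base=base, n_features=X.shape[1]
    )


def br_predict(ensemble: BrEnsemble, features: FeatureMatrix) -> np.ndarray:
    """Per-label binary predictions; empty prediction rows are allowed."""
    X = features.values
    _check_dimension(ensemble.n_features, X)
    cols = [
        np.asarray(model.predict(X), dtype=np.int8) for model in ensemble.models
    ]
    return np.column_stack(cols)


def save_ensemble(ensemble: RakelEnsemble, directory: str | Path) -> None:
    """Write a JSON manifest plus joblib per-model artifacts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": "rakel",
        "l": ensemble.l,
        "threshold": ensemble.threshold,
        "n_features": ensemble.n_features,
        "subsets": [list(s.indices) for s in ensemble.subsets],
        "class_inventories": [
            [sorted(cls) for cls in inv] for inv in ensemble.class_inventories
        ],
        "base": asdict(ensemble.base) if ensemble.base else None,
    }
    (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))
    for i, model in enumerate(ensemble.models):
        joblib.dump(model, directory / f"model_{i:03d}.joblib")


def load_ensemble(directory: str | Path) -> RakelEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "ensemble.json").read_text())
    if manifest["kind"] != "rakel":
        raise ValueError(f"not a rakel ensemble: {manifest['kind']!r}")
    models = [
        joblib.load(directory / f"model_{i:03d}.joblib")
        for i in range(len(manifest["subsets"]))
    ]
    return RakelEnsemble(
        subsets=[LabelSubset(tuple(s)) for s in manifest["subsets"]],
        models=models,
        class_inventories=[
            [frozenset(cls) for cls in inv]
            for inv in manifest["class_inventories"]
        ],
        l=manifest["l"],
        threshold=manifest["threshold"],
        base=BaseClassifierSpec(**manifest["base"]) if manifest["base"] else None,
        n_features=manifest["n_features"],
    )
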