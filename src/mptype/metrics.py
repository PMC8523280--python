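"""Multilabel evaluation: exact match, Jaccard accuracy, hamming loss,
and their product-form integrated score.

With L_i the true label set and L_i' the predicted label set of sample i,
over n samples and m_labels possible labels:

    exact match  = (1/n) Σ 1[L_i = L_i']
    accuracy     = (1/n) Σ |L_i ∩ L_i'| / |L_i ∪ L_i'|      (Jaccard)
    hamming loss = (1/n) Σ |L_i Δ L_i'| / m_labels          (Δ = sym. diff.)

    integrated score = exact match × accuracy × (1 − hamming loss)

The integrated score compresses the three measurements into one
model-selection criterion; higher is better for everything but hamming
loss, whose complement enters the product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

LabelSets = Sequence[frozenset[int] | set[int]]


def label_sets(indicators: np.ndarray) -> list[frozenset[int]]:
    """Convert an n x m binary indicator matrix to per-sample label sets."""
    indicators = np.asarray(indicators)
    return [frozenset(map(int, np.flatnonzero(row))) for row in indicators]


def _check_lengths(true_labels: LabelSets, pred_labels: LabelSets) -> int:
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(pred_labels)} predicted"
        )
    if len(true_labels) == 0:
        raise ValueError("need at least one sample")
    return len(true_labels)


def exact_match(true_labels: LabelSets, pred_labels: LabelSets) -> float:
    """Fraction of samples whose predicted set equals the true set exactly."""
    n = _check_lengths(true_labels, pred_labels)
    return sum(set(t) == set(p) for t, p in zip(true_labels, pred_labels)) / n


def accuracy_jaccard(true_labels: LabelSets, pred_labels: LabelSets) -> float:
    """Mean per-sample Jaccard index |∩| / |∪|.

    A sample where both sets are empty contributes 1: a perfectly predicted
    empty set is not an error (the 0/0 case never arises in the membrane
    problem, where every protein has at least one type).
    """
    n = _check_lengths(true_labels, pred_labels)
    total = 0.0
    for t, p in zip(true_labels, pred_labels):
        t, p = set(t), set(p)
        union = t | p
        total += len(t & p) / len(union) if union else 1.0
    return total / n


def hamming_loss(
    true_labels: LabelSets, pred_labels: LabelSets, m_labels: int
) -> float:
    """Mean symmetric-difference size over the m_labels label universe."""
    n = _check_lengths(true_labels, pred_labels)
    if m_labels < 1:
        raise ValueError("m_labels must be >= 1")
    total = 0.0
    for t, p in zip(true_labels, pred_labels):
        t, p = set(t), set(p)
        if any(x >= m_labels or x < 0 for x in t | p):
            raise ValueError(f"label index outside [0, {m_labels})")
        total += len(t ^ p) / m_labels
    return total / n


def integrated_score(
    exact_match: float, accuracy: float, hamming_loss: float
) -> float:
    """exact match × accuracy × (1 − hamming loss)."""
    for name, v in (
        ("exact_match", exact_match),
        ("accuracy", accuracy),
        ("hamming_loss", hamming_loss),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return exact_match * accuracy * (1.0 - hamming_loss)


@dataclass
class MetricsRecord:
    """The four measurements for one evaluation, plus problem size."""

    exact_match: float
    accuracy: float
    hamming_loss: float
    integrated_score: float
    n: int
    m_labels: int

    def __post_init__(self) -> None:
        prod = self.exact_match * self.accuracy * (1.0 - self.hamming_loss)
        if abs(prod - self.integrated_score) > 1e-9:
            raise ValueError("integrated_score violates the product identity")

    @classmethod
    def from_sets(
        cls, true_labels: LabelSets, pred_labels: LabelSets, m_labels: int
    ) -> "MetricsRecord":
        em = exact_match(true_labels, pred_labels)
        acc = accuracy_jaccard(true_labels, pred_labels)
        hl = hamming_loss(true_labels, pred_labels, m_labels)
        return cls(
            exact_match=em,
            accuracy=acc,
            hamming_loss=hl,
            integrated_score=integrated_score(em, acc, hl),
            n=len(true_labels),
            m_labels=m_labels,
        )

    @classmethod
    def from_matrices(
        cls, true_matrix: np.ndarray, pred_matrix: np.ndarray
    ) -> "MetricsRecord":
        true_matrix = np.asarray(true_matrix)
        pred_matrix = np.asarray(pred_matrix)
        if true_matrix.shape != pred_matrix.shape:
            raise ValueError("indicator matrices must share a shape")
        return cls.from_sets(
            label_sets(true_matrix),
            label_sets(pred_matrix),
            m_labels=true_matrix.shape[1],
        )

    def rounded(self) -> dict:
        """Table-style reporting: 3 decimals, integrated score 4 decimals."""
        return {
            "exact_match": round(self.exact_match, 3),
            "accuracy": round(self.accuracy, 3),
            "hamming_loss": round(self.hamming_loss, 3),
            "integrated_score": round(self.integrated_score, 4),
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)
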