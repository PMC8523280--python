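"""Synthetic annotation/label datasets with the study's statistical shape.

The generator emulates a corpus of opaque domain tokens annotated on
proteins that carry one to three of six membrane-type labels with a heavily
skewed multiplicity distribution (about 97% single-label).  Each type owns
a pool of type-specific terms; a shared background pool models
uninformative domains.  The ``signal`` fraction controls how many of a
protein's terms come from its own types' pools versus background, so label
recoverability can be dialled from impossible (signal 0) to exact
(signal 1 with disjoint pools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mptype.annotation_io import MEMBRANE_TYPES, AnnotationTable, LabelMatrix

#: Multiplicity distribution of the real 2729-protein study data:
#: 2652 single-type, 73 two-type, 4 three-type proteins.
STUDY_MULTIPLICITY_PROBS: tuple[float, float, float] = (
    2652 / 2729, 73 / 2729, 4 / 2729,
)


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults mirror the real study's structure."""

    n_proteins: int = 2729
    l: int = 6
    pool_size: int = 25
    background_size: int = 50
    multiplicity_probs: tuple[float, ...] = STUDY_MULTIPLICITY_PROBS
    terms_per_protein: tuple[int, int] = (2, 6)
    signal: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ValueError("multiplicity_probs must sum to 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if self.terms_per_protein[0] < 1:
            raise ValueError("terms_per_protein lower bound must be >= 1")
        if self.terms_per_protein[0] > self.terms_per_protein[1]:
            raise ValueError("terms_per_protein range is inverted")
        if len(self.multiplicity_probs) > self.l:
            raise ValueError("multiplicity cannot exceed the label count")

    def label_names(self) -> list[str]:
        if self.l == len(MEMBRANE_TYPES):
            return list(MEMBRANE_TYPES)
        return [f"type-{i + 1}" for i in range(self.l)]

    def pools(self) -> list[list[str]]:
        """Disjoint per-type term pools, e.g. DOM1-017 for type pool 1."""
        return [
            [f"DOM{t + 1}-{i:03d}" for i in range(self.pool_size)]
            for t in range(self.l)
        ]

    def background(self) -> list[str]:
        return [f"BG-{i:03d}" for i in range(self.background_size)]


def generate_dataset(spec: SyntheticSpec) -> tuple[AnnotationTable, LabelMatrix]:
    """Draw a (AnnotationTable, LabelMatrix) pair, deterministic given seed.

    Each protein draws its multiplicity from ``multiplicity_probs``, its
    types uniformly without replacement, its term count uniformly from
    ``terms_per_protein``, and each term from the union of its types' pools
    with probability ``signal`` (else from background).  Duplicate draws
    collapse, so every protein ends with 1..terms_per_protein[1] unique
    terms.
    """
    rng = np.random.default_rng(spec.seed)
    pools = spec.pools()
    background = spec.background()
    label_names = spec.label_names()

    protein_ids = [f"SP{i:05d}" for i in range(spec.n_proteins)]
    terms: dict[str, list[str]] = {}
    indicators = np.zeros((spec.n_proteins, spec.l), dtype=np.int8)

    mult_values = np.arange(1, len(spec.multiplicity_probs) + 1)
    lo, hi = spec.terms_per_protein
    for i, pid in enumerate(protein_ids):
        mult = int(rng.choice(mult_values, p=spec.multiplicity_probs))
        types = rng.choice(spec.l, size=mult, replace=False)
        indicators[i, types] = 1
        own_pool = [t for ty in sorted(types) for t in pools[ty]]
        n_terms = int(rng.integers(lo, hi + 1))
        is_signal = [
            rng.random() < spec.signal or not background
            for _ in range(n_terms)
        ]
        # signal terms cover each of the protein's types first (so the term
        # set identifies the type set whenever the budget allows), then draw
        # uniformly from the union of its pools
        cover = list(rng.permutation(np.sort(types)))[: sum(is_signal)]
        drawn: dict[str, None] = {}
        for use_signal in is_signal:
            if use_signal:
                if cover:
                    pool = pools[int(cover.pop())]
                    source = pool
                else:
                    source = own_pool
            else:
                source = background
            drawn.setdefault(source[int(rng.integers(len(source)))], None)
        terms[pid] = list(drawn)

    return (
        AnnotationTable(protein_ids, terms),
        LabelMatrix(protein_ids, label_names, indicators),
    )


def generate_fixture_small() -> tuple[AnnotationTable, LabelMatrix]:
    """Frozen 12-protein, 3-label, 9-term dataset for unit tests and docs.

    Ten proteins carry one label, one carries two, one carries all three,
    so the multiplicity distribution is {1: 10, 2: 1, 3: 1}.
    """
    term_table = {
        "P01": ["A1", "A2"],
        "P02": ["A1", "A3"],
        "P03": ["A2", "A3"],
        "P04": ["A1"],
        "P05": ["B1", "B2"],
        "P06": ["B1", "B3"],
        "P07": ["B2"],
        "P08": ["C1", "C2"],
        "P09": ["C1", "C3"],
        "P10": ["C2", "C3"],
        "P11": ["A1", "B1"],
        "P12": ["A2", "B2", "C1"],
    }
    rows = {
        "P01": (1, 0, 0), "P02": (1, 0, 0), "P03": (1, 0, 0),
        "P04": (1, 0, 0), "P05": (0, 1, 0), "P06": (0, 1, 0),
        "P07": (0, 1, 0), "P08": (0, 0, 1), "P09": (0, 0, 1),
        "P10": (0, 0, 1), "P11": (1, 1, 0), "P12": (1, 1, 1),
    }
    pids = list(term_table)
    annotations = AnnotationTable(pids, {p: list(t) for p, t in term_table.items()})
    labels = LabelMatrix(
        pids,
        ["alpha", "beta", "gamma"],
        np.array([rows[p] for p in pids], dtype=np.int8),
    )
    return annotations, labels
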