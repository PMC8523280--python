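"""Reading, writing and filtering of protein annotation and type-label tables.

Two plain-text tab-separated formats are supported:

* annotation TSV, pair-per-line dialect: ``protein_id<TAB>term_id`` (one
  protein--domain pair per line, InterPro protein2ipr style), or the
  terms-list dialect ``protein_id<TAB>term1,term2,...``;
* label TSV: ``protein_id<TAB>type1[;type2[;type3]]``.

Lines starting with ``#`` are comments.  Protein and term identifiers are
opaque strings: the same machinery serves InterPro domain terms, GO terms or
pathway identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The six membrane-protein types of the classification problem, in the
#: canonical column order used throughout the package.
MEMBRANE_TYPES: tuple[str, ...] = (
    "GPI-anchor",
    "lipid-anchor",
    "multipass",
    "peripheral",
    "single-pass-type-I",
    "single-pass-type-II",
)


class ParseError(ValueError):
    """A malformed line in an annotation or label file."""


@dataclass
class AnnotationTable:
    """Protein -> functional-domain term annotation relation.

    Every retained protein maps to at least one term; protein ids are unique
    and each protein's term list holds no duplicates (first occurrence wins).
    """

    protein_ids: list[str]
    terms: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.protein_ids) != len(set(self.protein_ids)):
            raise ValueError("duplicate protein ids in AnnotationTable")
        for pid in self.protein_ids:
            tl = self.terms.get(pid, [])
            if not tl:
                raise ValueError(f"protein {pid!r} has no terms")
            if len(tl) != len(set(tl)):
                raise ValueError(f"duplicate terms for protein {pid!r}")

    def __len__(self) -> int:
        return len(self.protein_ids)

    def vocabulary(self) -> list[str]:
        """All distinct terms, in first-occurrence order across proteins."""
        seen: dict[str, None] = {}
        for pid in self.protein_ids:
            for t in self.terms[pid]:
                seen.setdefault(t, None)
        return list(seen)

    def subset(self, protein_ids: Sequence[str]) -> "AnnotationTable":
        keep = set(protein_ids)
        order = [p for p in self.protein_ids if p in keep]
        return AnnotationTable(order, {p: list(self.terms[p]) for p in order})


@dataclass
class LabelMatrix:
    """Protein x type binary indicator matrix.

    Rows align with ``protein_ids``; columns with ``label_names``.  Every
    row has at least one positive entry (every protein belongs to at least
    one type).
    """

    protein_ids: list[str]
    label_names: list[str]
    indicators: np.ndarray

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=np.int8)
        n, l = self.indicators.shape
        if n != len(self.protein_ids):
            raise ValueError("row count does not match protein_ids")
        if l != len(self.label_names):
            raise ValueError("column count does not match label_names")
        if len(self.protein_ids) != len(set(self.protein_ids)):
            raise ValueError("duplicate protein ids in LabelMatrix")
        if not np.isin(self.indicators, (0, 1)).all():
            raise ValueError("indicators must be binary")
        if n and not (self.indicators.sum(axis=1) >= 1).all():
            raise ValueError("every protein must belong to at least one type")

    def __len__(self) -> int:
        return len(self.protein_ids)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def label_sets(self) -> list[frozenset[int]]:
        """Per-protein sets of positive label indices."""
        return [frozenset(map(int, np.flatnonzero(row))) for row in self.indicators]

    def subset(self, protein_ids: Sequence[str]) -> "LabelMatrix":
        keep = set(protein_ids)
        idx = [i for i, p in enumerate(self.protein_ids) if p in keep]
        return LabelMatrix(
            [self.protein_ids[i] for i in idx],
            list(self.label_names),
            self.indicators[idx],
        )


@dataclass
class LabelSummary:
    """Bookkeeping counts over a LabelMatrix.

    ``total_assignments`` equals both the sum of per-type counts and the
    multiplicity-weighted protein counts; the constructor enforces this
    conservation identity.
    """

    per_type_counts: dict[str, int]
    total_assignments: int
    multiplicity_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s1 = sum(self.per_type_counts.values())
        s2 = sum(k * v for k, v in self.multiplicity_counts.items())
        if not (s1 == s2 == self.total_assignments):
            raise ValueError(
                f"inconsistent summary: per-type sum {s1}, "
                f"multiplicity-weighted sum {s2}, total {self.total_assignments}"
            )

    @property
    def n_proteins(self) -> int:
        return sum(self.multiplicity_counts.values())


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def read_annotations(
    path: str | Path, dialect: str = "pair-per-line"
) -> AnnotationTable:
    """Read an annotation TSV into an :class:`AnnotationTable`.

    Duplicate (protein, term) pairs collapse; term order within a protein is
    first-occurrence order.  Raises :class:`ParseError` naming the line
    number on a malformed line, and on an empty file.
    """
    if dialect not in ("pair-per-line", "terms-list"):
        raise ValueError(f"unknown dialect {dialect!r}")
    order: list[str] = []
    terms: dict[str, dict[str, None]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}: malformed line {lineno}: {line!r}")
        pid = fields[0]
        if dialect == "pair-per-line":
            new_terms = [fields[1]]
        else:
            new_terms = [t for t in fields[1].split(",") if t]
            if not new_terms:
                raise ParseError(f"{path}: malformed line {lineno}: {line!r}")
        if pid not in terms:
            order.append(pid)
            terms[pid] = {}
        for t in new_terms:
            terms[pid].setdefault(t, None)
    if not order:
        raise ParseError(f"{path}: no annotation records found")
    return AnnotationTable(order, {p: list(d) for p, d in terms.items()})


def write_annotations(
    table: AnnotationTable, path: str | Path, dialect: str = "pair-per-line"
) -> None:
    """Write an :class:`AnnotationTable` in either TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in table.protein_ids:
            if dialect == "pair-per-line":
                for t in table.terms[pid]:
                    fh.write(f"{pid}\t{t}\n")
            elif dialect == "terms-list":
                fh.write(f"{pid}\t{','.join(table.terms[pid])}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_labels(path: str | Path, label_names: Sequence[str]) -> LabelMatrix:
    """Read a label TSV into a :class:`LabelMatrix`.

    Each line is ``protein_id<TAB>type1[;type2[;...]]``; every type name
    must be in ``label_names``.  Duplicate protein lines merge by set-union
    of their label sets.
    """
    name_to_col = {name: j for j, name in enumerate(label_names)}
    order: list[str] = []
    rows: dict[str, set[int]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0]:
            raise ParseError(f"{path}: malformed line {lineno}: {line!r}")
        pid = fields[0]
        names = [t for t in fields[1].split(";") if t]
        if not names:
            raise ParseError(
                f"{path}: line {lineno}: protein {pid!r} has zero types"
            )
        for name in names:
            if name not in name_to_col:
                raise ParseError(
                    f"{path}: line {lineno}: unknown type name {name!r}"
                )
        if pid not in rows:
            order.append(pid)
            rows[pid] = set()
        rows[pid].update(name_to_col[name] for name in names)
    if not order:
        raise ParseError(f"{path}: no label records found")
    mat = np.zeros((len(order), len(label_names)), dtype=np.int8)
    for i, pid in enumerate(order):
        mat[i, sorted(rows[pid])] = 1
    return LabelMatrix(order, list(label_names), mat)


def write_labels(labels: LabelMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, row in zip(labels.protein_ids, labels.indicators):
            names = [labels.label_names[j] for j in np.flatnonzero(row)]
            fh.write(f"{pid}\t{';'.join(names)}\n")


def filter_annotated(
    labels: LabelMatrix, annotations: AnnotationTable
) -> tuple[LabelMatrix, AnnotationTable, int]:
    """Drop labeled proteins that lack domain annotations (and vice versa).

    Both outputs are restricted to proteins present in both inputs, with
    relative order preserved; the third element is the number of labeled
    proteins dropped.  Raises ``ValueError`` if no protein survives.
    """
    annotated = set(annotations.protein_ids)
    kept = [p for p in labels.protein_ids if p in annotated]
    if not kept:
        raise ValueError("no labeled protein has domain annotations")
    dropped = len(labels) - len(kept)
    if dropped:
        logger.info("filter_annotated: dropped %d unannotated proteins", dropped)
    return labels.subset(kept), annotations.subset(kept), dropped


def summarize_labels(labels: LabelMatrix) -> LabelSummary:
    """Per-type counts, total assignments and the multiplicity distribution."""
    per_type = {
        name: int(labels.indicators[:, j].sum())
        for j, name in enumerate(labels.label_names)
    }
    mults = labels.indicators.sum(axis=1)
    uniq, counts = np.unique(mults, return_counts=True)
    return LabelSummary(
        per_type_counts=per_type,
        total_assignments=int(mults.sum()),
        multiplicity_counts={int(k): int(v) for k, v in zip(uniq, counts)},
    )
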