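"""Domain-sentence corpus, term embeddings and protein feature vectors.

The encoding treats a protein's functional-domain terms as the words of a
sentence and the annotation table as a corpus.  Term vectors trained on
that corpus are averaged per protein into a dense feature vector; the
classical sparse alternative is a one-hot bag-of-domains encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mptype.annotation_io import AnnotationTable
from mptype.word2vec import EmptyVocabularyError, train_cbow

logger = logging.getLogger(__name__)

DEFAULT_HYPERPARAMETERS: dict = {
    "architecture": "cbow",
    "window": 5,
    "min_count": 1,
    "epochs": 5,
    "negative": 5,
    "full_window": False,
}


@dataclass
class Corpus:
    """One sentence (token list) per protein; every sentence is non-empty."""

    sentences: list[list[str]]

    def __post_init__(self) -> None:
        if any(not s for s in self.sentences):
            raise ValueError("corpus sentences must be non-empty")

    def __len__(self) -> int:
        return len(self.sentences)

    def vocabulary(self) -> set[str]:
        return {tok for sent in self.sentences for tok in sent}


@dataclass
class EmbeddingTable:
    """Term -> d-dimensional vector mapping with its training provenance."""

    dimension: int
    vectors: dict[str, np.ndarray]
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, v in self.vectors.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {tok!r} has shape {v.shape}, "
                    f"expected ({self.dimension},)"
                )
            self.vectors[tok] = v

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors


@dataclass
class FeatureMatrix:
    """Protein feature rows, from embedding averaging or one-hot encoding."""

    protein_ids: list[str]
    values: np.ndarray
    scheme: str = "embedding-average"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.protein_ids):
            raise ValueError("row count does not match protein_ids")
        if self.scheme not in ("embedding-average", "one-hot"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "one-hot" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("one-hot features must be binary")

    def __len__(self) -> int:
        return len(self.protein_ids)

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def build_corpus(
    annotations: AnnotationTable, ordering: str = "lexicographic"
) -> Corpus:
    """One sentence per protein, in protein order.

    ``ordering="lexicographic"`` sorts each sentence's tokens (domain sets
    are unordered, and sorting makes the corpus independent of annotation
    file shufflings); ``"file-order"`` keeps first-occurrence order.
    """
    if ordering not in ("lexicographic", "file-order"):
        raise ValueError(f"unknown ordering {ordering!r}")
    sents = []
    for pid in annotations.protein_ids:
        toks = list(annotations.terms[pid])
        if ordering == "lexicographic":
            toks.sort()
        sents.append(toks)
    return Corpus(sents)


def train_domain_embeddings(
    corpus: Corpus,
    dimension: int,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
) -> EmbeddingTable:
    """Train one vector per domain term on the sentence corpus.

    Deterministic given (seed, single worker).  Hyperparameters default to
    CBOW, window 5, 5 negative samples, 5 epochs and min_count 1; whatever
    was used is recorded in the returned table.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        hp.update(hyperparameters)
    if hp["architecture"] != "cbow":
        raise ValueError(f"unsupported architecture {hp['architecture']!r}")
    try:
        vocab, W = train_cbow(
            corpus.sentences,
            dimension,
            window=hp["window"],
            negative=hp["negative"],
            epochs=hp["epochs"],
            min_count=hp["min_count"],
            full_window=hp["full_window"],
            seed=seed,
        )
    except EmptyVocabularyError:
        raise EmptyVocabularyError(
            f"vocabulary empty after min_count={hp['min_count']} filtering; "
            "retry with min_count=1"
        )
    return EmbeddingTable(
        dimension=dimension,
        vectors={tok: W[i] for i, tok in enumerate(vocab)},
        hyperparameters={**hp, "seed": seed, "dimension": dimension},
    )


def protein_vectors(
    annotations: AnnotationTable, embeddings: EmbeddingTable
) -> FeatureMatrix:
    """Average each protein's in-vocabulary term vectors into one row.

    Terms absent from the embedding vocabulary are skipped; a protein whose
    terms are all out-of-vocabulary gets the zero vector (with a warning)
    rather than being dropped — exclusion of unannotated proteins happens
    upstream, once.
    """
    if len(embeddings) == 0:
        raise ValueError("embedding table is empty")
    rows = np.zeros((len(annotations), embeddings.dimension))
    n_zero = 0
    for i, pid in enumerate(annotations.protein_ids):
        vecs = [
            embeddings.vectors[t]
            for t in annotations.terms[pid]
            if t in embeddings
        ]
        if vecs:
            rows[i] = np.mean(vecs, axis=0)
        else:
            n_zero += 1
            logger.warning(
                "protein %s has no in-vocabulary terms; zero vector", pid
            )
    if n_zero:
        logger.warning("%d proteins received zero vectors", n_zero)
    return FeatureMatrix(
        list(annotations.protein_ids), rows, scheme="embedding-average"
    )


def one_hot_encode(
    annotations: AnnotationTable, vocabulary: Sequence[str]
) -> FeatureMatrix:
    """Binary protein x vocabulary matrix: 1 iff the term is annotated."""
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    col = {t: j for j, t in enumerate(vocabulary)}
    rows = np.zeros((len(annotations), len(vocabulary)))
    n_oov = 0
    for i, pid in enumerate(annotations.protein_ids):
        for t in annotations.terms[pid]:
            if t in col:
                rows[i, col[t]] = 1.0
            else:
                n_oov += 1
    if n_oov:
        logger.info("one_hot_encode: ignored %d out-of-vocabulary terms", n_oov)
    return FeatureMatrix(list(annotations.protein_ids), rows, scheme="one-hot")


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Serialize in word2vec text format: header ``|V| d``, one term per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for tok, vec in table.vectors.items():
            fh.write(tok + " " + " ".join(f"{x:.17g}" for x in vec) + "\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != n:
        raise ValueError(f"expected {n} vectors, found {len(vectors)}")
    return EmbeddingTable(dimension=d, vectors=vectors)


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    """TSV with protein_id first; 17 significant digits round-trip floats."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scheme={features.scheme}\n")
        for pid, row in zip(features.protein_ids, features.values):
            fh.write(pid + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def read_features(path: str | Path) -> FeatureMatrix:
    scheme = "embedding-average"
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# scheme="):
                scheme = line.split("=", 1)[1]
                continue
            if not line:
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return FeatureMatrix(ids, np.array(rows), scheme=scheme)
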