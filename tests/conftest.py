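import numpy as np
import pytest

from mptype.annotation_io import MEMBRANE_TYPES, LabelMatrix
from mptype.embedding import FeatureMatrix, build_corpus, train_domain_embeddings
from mptype.synthetic import generate_fixture_small


@pytest.fixture(scope="session")
def small_dataset():
    return generate_fixture_small()


@pytest.fixture(scope="session")
def small_embeddings(small_dataset):
    annotations, _ = small_dataset
    corpus = build_corpus(annotations)
    return train_domain_embeddings(corpus, 8, seed=42)


@pytest.fixture()
def toy_labels():
    """Two proteins over the six membrane types: one single-, one two-label."""
    mat = np.zeros((2, 6), dtype=np.int8)
    mat[0, 2] = 1          # multipass
    mat[1, [0, 1]] = 1     # GPI-anchor + lipid-anchor
    return LabelMatrix(["P1", "P2"], list(MEMBRANE_TYPES), mat)


def random_multilabel_problem(rng, n, l, n_features=3):
    """Random dataset with unique feature rows and non-empty label sets."""
    X = rng.random((n, n_features))
    Y = rng.integers(0, 2, size=(n, l)).astype(np.int8)
    for row in Y:  # every sample needs >= 1 label
        if row.sum() == 0:
            row[rng.integers(l)] = 1
    features = FeatureMatrix([f"S{i}" for i in range(n)], X)
    labels = LabelMatrix(
        [f"S{i}" for i in range(n)], [f"L{j}" for j in range(l)], Y
    )
    return features, labels
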