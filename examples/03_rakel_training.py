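"""Fit a RAKEL ensemble on protein features and score its predictions.

RAKEL draws m random k-subsets of the labels, trains one power-set
classifier per subset, and assigns a label when more than half of the
classifiers involving it vote for it.
"""

from mptype import (
    BaseClassifierSpec,
    MetricsRecord,
    SyntheticSpec,
    build_corpus,
    generate_dataset,
    protein_vectors,
    rakel_fit,
    rakel_predict,
    train_domain_embeddings,
)

annotations, labels = generate_dataset(SyntheticSpec(n_proteins=300, seed=3))
embeddings = train_domain_embeddings(build_corpus(annotations), 50, seed=3)
features = protein_vectors(annotations, embeddings)

base = BaseClassifierSpec(algorithm="random_forest", trees=100, seed=3)
ensemble = rakel_fit(features, labels, base, k=6, m=10, seed=3)
proportions, predictions = rakel_predict(ensemble, features)

record = MetricsRecord.from_matrices(labels.indicators, predictions)
print(f"ensemble: {ensemble.m} models over subsets of size 6")
print(f"training-set metrics: {record.rounded()}")
# Training-set scores are optimistic by construction; see the
# cross-validation example for honest out-of-fold numbers.
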