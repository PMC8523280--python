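"""Small grid search over embedding dimension, k and forest size.

The full study grid is 10 dimensions x 5 k-values x 5 tree counts; this
example runs a 2 x 2 x 2 corner of it and reports the winner by
integrated score (ties break toward the simpler model).
"""

from mptype import (
    BaseClassifierSpec,
    GridConfig,
    SyntheticSpec,
    build_corpus,
    generate_dataset,
    grid_search,
    protein_vectors,
    train_domain_embeddings,
)

annotations, labels = generate_dataset(SyntheticSpec(n_proteins=200, seed=1))
corpus = build_corpus(annotations)
features_by_dim = {
    d: protein_vectors(annotations, train_domain_embeddings(corpus, d, seed=1))
    for d in (25, 50)
}
grid = [
    GridConfig(dimension=d, k=k, m_subsets=10,
               base=BaseClassifierSpec(trees=t, seed=1))
    for d in (25, 50) for k in (3, 6) for t in (50, 100)
]
best, results = grid_search(features_by_dim, labels, grid, seed=11)

for r in results:
    print(f"d={r.config.dimension:3d} k={r.config.k} "
          f"trees={r.config.base.trees:3d} -> "
          f"integrated score {r.record.integrated_score:.4f}")
print(f"best: d={best.config.dimension}, k={best.config.k}, "
      f"trees={best.config.base.trees}, "
      f"integrated score {best.record.integrated_score:.4f}")
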