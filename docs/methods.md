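# Methods

## Problem and data model

A protein is described by two tables: an annotation table mapping each
protein to one or more opaque functional-domain terms (InterPro-style
`protein_id → IPR...` pairs; the identifiers are never parsed, so GO terms
or pathway identifiers work identically), and a label table assigning each
protein one to three of six membrane-protein types. Proteins without any
domain annotation carry no usable signal and are excluded once, up front,
by `filter_annotated`; no other sample filtering happens anywhere in the
pipeline. Label files merge duplicate protein lines by set-union, the only
lossless choice.

## Feature extraction

Domain terms are treated as words and each protein's term list as a
sentence. `train_domain_embeddings` trains CBOW vectors with negative
sampling on that corpus using the package's own single-threaded numpy
trainer (`mptype.word2vec`): for every position, the mean of the context
vectors is pushed toward the center word and away from `negative` noise
words sampled from the unigram distribution to the 3/4 power, with a
linearly decaying learning rate (0.025 → 1e-4). Defaults: CBOW
architecture, window 5, 5 negative samples, 5 epochs, `min_count=1`.

`min_count=1` deviates deliberately from the common default of 5: domain
sentences are short and rare domains are informative, and a larger cutoff
would silently zero out proteins whose every term is rare. An optional
`full_window` mode uses the entire sentence as context at every position,
since domain sets are unordered and window truncation of a sorted token
list is arbitrary; the default stays at window 5. Sentence tokens are
sorted lexicographically by default so the corpus — and therefore the
embedding — is independent of annotation-file ordering; `file-order` is
available.

A protein's feature vector is the arithmetic mean of its in-vocabulary
term vectors. Out-of-vocabulary terms are skipped; a protein with no
in-vocabulary term gets the zero vector and a logged warning rather than
being dropped, keeping featurization total. `one_hot_encode` provides the
binary bag-of-domains baseline over an explicit vocabulary.

Embeddings are trained once on the full annotation corpus, outside the
cross-validation folds. This is sound because training consumes only term
co-occurrence — type labels never enter — so no label information can leak
into held-out folds.

## RAKEL

`sample_label_subsets(l, k, m, seed)` draws m size-k label subsets,
without replacement from all C(l, k) subsets while enough exist, otherwise
with replacement (logged). The with-replacement fallback is required, not
an edge case: the best-performing configuration is k = l = 6 with m = 10,
where only one 6-subset exists and all ten models share it. Duplicate-
subset models are decorrelated purely through base-classifier randomness,
which is why each model's seed is offset by its index.

For each subset, every training sample's label set is intersected with the
subset and the resulting power-set member (possibly empty) becomes one
categorical class. Observed classes are coded in a canonical order — by
class size, then sorted members — so base-classifier tie-breaking is
independent of sample order; with k = 1 this makes the empty class code 0
and the singleton code 1, exactly the binary encoding Binary Relevance
uses, which is what makes the k = 1 reduction to BR hold even on majority
ties. Classes unseen in training are simply never predictable, the
standard problem-transformation semantics.

At prediction time, label j's vote proportion is the number of models
whose subset contains j *and* whose predicted class includes j, divided by
the number of models whose subset contains j (0 if uncovered). A label is
assigned iff its proportion **strictly exceeds** the 0.5 threshold: a
proportion of exactly 0.5 — possible whenever the coverage count is even —
is a negative. This choice follows the "higher than" reading of the vote
rule and is worth knowing about because it visibly increases empty
predictions when base classifiers disagree. Empty predicted label sets are
returned as-is (no argmax fallback) and counted in the log.

Base classifiers satisfy a two-method contract (`fit(X, y)` integer
codes, `predict(X)` codes) and are scikit-learn estimators: random forest
(default, 500 trees), polynomial-kernel SVM (C, exponent) and RBF-kernel
SVM (C, gamma). A `MemorizingClassifier` (exact feature-row recall,
majority fallback) exists for verification: it isolates the ensemble's
transformation and voting logic from base-classifier behaviour in tests.

## Evaluation protocol

`kfold_indices` makes plain random partitions with fold sizes differing by
at most one — no stratification, since nothing in the protocol requires
it. Each fold is predicted by a model trained on the other nine and all n
out-of-fold predictions are pooled into a single metrics computation, so
every sample is predicted exactly once (asserted). The four measurements
are exact match, Jaccard accuracy, hamming loss over the m_labels
universe, and their product-form integrated score. The Jaccard term for a
sample where both sets are empty is defined as 1 (a perfectly predicted
empty set is not an error; the 0/0 case cannot arise on the membrane data,
where every protein has at least one type). Reported tables round the
measurements to 3 decimals and the integrated score to 4.

`grid_search` evaluates every configuration by CV at a shared fold seed
and picks the highest integrated score, breaking ties toward the simpler
model (fewer trees, then smaller dimension, then smaller k). The
full-scale study grid is 10 embedding dimensions (50–500 step 50) × k ∈
{2..6} × m = 10 × 5 tree counts (100–500 step 100) = 250 configurations.

## Synthetic data generator

`generate_dataset` emulates the structure of the real 2729-protein study
data, not its content: six types with the real names, multiplicity drawn
from (2652, 73, 4)/2729 (~97% single-type, capped at three types), types
uniform without replacement, and per-protein term counts uniform on 2–6.
Each type owns a disjoint pool of 25 synthetic terms; 50 background terms
are shared by all types and model uninformative domains. Each term draw is
a signal draw with probability `signal` (default 0.8) and a background
draw otherwise; signal draws cover each of the protein's types once before
sampling uniformly from the union of its pools, so at `signal=1` and a
term budget of at least the protein's multiplicity the term set identifies
the type set exactly. Everything is drawn from one seeded generator and is
bit-reproducible.

What the generator does **not** emulate: the heavy-tailed frequency
distribution of real IPR terms, domain co-occurrence structure beyond
type membership, and between-type annotation imbalance. Passing tests
therefore demonstrate that the pipeline recovers planted signal under the
study's label structure — not that it attains any particular accuracy on
real UniProt/InterPro data, which would require the original downloads.

At full signal the end-to-end tenfold exact match exceeds 0.9 at n = 500
with 50-dimensional embeddings and the published classifier configuration
(k = 6, m = 10, 500 trees); at zero signal it collapses to the
neighbourhood of the majority-label-set frequency, the no-information
baseline. These two regimes bracket the generator's intended use as a
pipeline validity check. Problem sizes in the test suite (n ≤ 500, d ≤ 50,
10 folds) were chosen as the smallest at which these regimes separate
cleanly.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.default_rng` seeds; the CLI
  expands one global seed into per-stage seeds by hashing stage names, so
  stages are independently reproducible.
- The embedding trainer is single-threaded by design; random forests run
  with `n_jobs=1`. Identical seeds give bit-identical embeddings, subsets,
  folds and forest predictions.
- Embedding tables serialize in the word2vec text format (`|V| d` header),
  feature matrices as TSV at 17 significant digits; both round-trip
  bit-exactly. Trained ensembles serialize to a directory with a JSON
  manifest (subsets, threshold, class inventories, base spec) plus one
  joblib artifact per model.
- Degenerate inputs: a subset whose training classes collapse to one class
  becomes a constant predictor (logged), as does a single-class label
  column in Binary Relevance; an empty vocabulary after `min_count`
  filtering raises with advice to use `min_count=1`.

## Known limitations

- The vote threshold's strict inequality makes results at even coverage
  counts sensitive to single-model flips; this is inherent to the voting
  rule, not an implementation artifact.
- Grid search retrains embeddings per dimension but shares one fold seed
  across configurations; per-configuration fold resampling would add
  variance without changing the argmax in expectation.
- SVM base classifiers delegate to scikit-learn's SVC, whose optimizer
  differs from sequential-minimal-optimization implementations elsewhere;
  identical hyperparameters need not reproduce third-party SVM numbers.
- Ranking-based multilabel measures (one-error, coverage, average
  precision) are out of scope.
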