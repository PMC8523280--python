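"""Seeded CBOW word-embedding trainer with negative sampling.

A self-contained numpy implementation of the continuous-bag-of-words model:
for each position in a sentence, the mean of the context word vectors is
trained to score the center word above ``negative`` noise words drawn from
the unigram distribution raised to the 3/4 power, by stochastic gradient
descent on the logistic loss with a linearly decaying learning rate.

Domain-annotation corpora are small (thousands of short sentences over a
vocabulary of a few thousand terms), so a single-threaded pure-numpy loop
is fast and, given a seed, bit-reproducible — which matters more here than
raw throughput.  Sentences are visited in corpus order; all randomness
(vector initialisation, window shrinking, negative draws) comes from one
``numpy`` generator.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np


class EmptyVocabularyError(ValueError):
    """No token survived the ``min_count`` frequency filter."""


def build_vocab(
    sentences: Sequence[Sequence[str]], min_count: int = 1
) -> tuple[list[str], np.ndarray]:
    """Vocabulary (most-frequent first, ties lexicographic) and counts."""
    counts = Counter(tok for sent in sentences for tok in sent)
    vocab = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab:
        raise EmptyVocabularyError(
            f"no token occurs >= {min_count} times; retry with min_count=1"
        )
    return vocab, np.array([counts[t] for t in vocab], dtype=np.float64)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_cbow(
    sentences: Sequence[Sequence[str]],
    dimension: int,
    *,
    window: int = 5,
    negative: int = 5,
    epochs: int = 5,
    min_count: int = 1,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    ns_exponent: float = 0.75,
    full_window: bool = False,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Train CBOW vectors; returns (vocabulary, |V| x dimension array).

    ``full_window=True`` uses the whole sentence as context at every
    position (no random window shrinking) — appropriate when sentences are
    unordered term sets rather than true word sequences.
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    vocab, counts = build_vocab(sentences, min_count)
    index = {t: i for i, t in enumerate(vocab)}
    encoded = [
        np.array([index[t] for t in sent if t in index], dtype=np.int64)
        for sent in sentences
    ]
    encoded = [s for s in encoded if len(s) > 0]

    rng = np.random.default_rng(seed)
    n_vocab = len(vocab)
    # input (word) vectors small-random, output (context) vectors zero
    W = (rng.random((n_vocab, dimension)) - 0.5) / dimension
    C = np.zeros((n_vocab, dimension))

    noise = counts**ns_exponent
    noise_cdf = np.cumsum(noise / noise.sum())

    total_words = sum(len(s) for s in encoded) * epochs
    processed = 0
    for _ in range(epochs):
        for sent in encoded:
            slen = len(sent)
            for pos in range(slen):
                lr = max(
                    min_alpha, alpha * (1.0 - processed / max(1, total_words))
                )
                processed += 1
                if full_window:
                    lo, hi = 0, slen
                else:
                    b = int(rng.integers(1, window + 1))
                    lo, hi = max(0, pos - b), min(slen, pos + b + 1)
                ctx = np.concatenate((sent[lo:pos], sent[pos + 1 : hi]))
                if len(ctx) == 0:
                    continue
                center = sent[pos]
                h = W[ctx].mean(axis=0)

                targets = np.empty(1 + negative, dtype=np.int64)
                targets[0] = center
                if negative:
                    draws = np.searchsorted(noise_cdf, rng.random(negative))
                    targets[1:] = draws
                labels = np.zeros(1 + negative)
                labels[0] = 1.0
                # a noise draw that hits the center word is skipped
                live = np.ones(1 + negative, dtype=bool)
                live[1:] = targets[1:] != center

                t_live = targets[live]
                g = (labels[live] - _sigmoid(C[t_live] @ h)) * lr
                err = g @ C[t_live]
                # accumulate output-vector updates; duplicates must add
                np.add.at(C, t_live, g[:, None] * h[None, :])
                W[ctx] += err / len(ctx)
    return vocab, W
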