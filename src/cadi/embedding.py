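"""Continuous bag-of-words (CBOW) word embeddings.

A compact numpy implementation of the CBOW training objective with negative
sampling: each token is predicted from the mean of its context-window input
vectors, and the input/output matrices are updated by stochastic gradient
descent on the logistic loss. Training is single-threaded and fully
deterministic under a fixed seed, which is what the downstream relevance
scores require for reproducible dictionary construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["EmbeddingSpace", "CBOWEmbedding", "train_embeddings"]


@dataclass
class EmbeddingSpace:
    """A fitted vocabulary and its word vectors.

    Attributes
    ----------
    words : list of str
        Vocabulary, in training order (descending frequency, ties lexicographic).
    matrix : ndarray of shape (n_words, dim)
        Input-layer vectors; these are the vectors used for similarity.
    dim : int
        Vector dimensionality.
    """

    words: list
    matrix: np.ndarray
    dim: int
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __len__(self) -> int:
        return len(self.words)

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self.index[word]]
        except KeyError:
            raise KeyError(f"word not in embedding vocabulary: {word!r}") from None

    def cosine(self, a: str, b: str) -> float:
        """Cosine similarity between the vectors of two vocabulary words."""
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(va @ vb / (na * nb))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class CBOWEmbedding(BaseEstimator):
    """CBOW word-embedding trainer with negative sampling.

    Parameters
    ----------
    dim : int, default 100
        Embedding dimensionality.
    window : int, default 5
        Maximum distance between the predicted word and a context word.
    epochs : int, default 20
        Number of passes over the corpus.
    min_count : int, default 2
        Words occurring fewer times are dropped from the vocabulary.
    negative : int, default 5
        Negative samples per positive example, drawn from the unigram
        distribution raised to 3/4.
    lr, min_lr : float
        Initial learning rate, decayed linearly to ``min_lr`` over training.
    seed : int, default 0
        Seed for initialisation and negative sampling.

    Attributes
    ----------
    space_ : EmbeddingSpace
        Fitted vocabulary and input vectors.
    vocab_counts_ : dict
        Corpus frequency of every vocabulary word.
    """

    def __init__(self, dim=100, window=5, epochs=20, min_count=2, negative=5,
                 lr=0.025, min_lr=1e-4, seed=0):
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.min_count = min_count
        self.negative = negative
        self.lr = lr
        self.min_lr = min_lr
        self.seed = seed

    def fit(self, sentences: Iterable[Sequence[str]], y=None) -> "CBOWEmbedding":
        sentences = [list(s) for s in sentences]
        if not sentences or all(len(s) == 0 for s in sentences):
            raise ValueError("cannot train embeddings on an empty corpus")
        if min(self.dim, self.window, self.epochs) < 1:
            raise ValueError("dim, window and epochs must all be >= 1")

        counts = Counter(w for s in sentences for w in s)
        vocab = sorted((w for w, c in counts.items() if c >= self.min_count),
                       key=lambda w: (-counts[w], w))
        if not vocab:
            raise ValueError(
                f"no word reaches min_count={self.min_count}; corpus too small")
        index = {w: i for i, w in enumerate(vocab)}
        encoded = [np.array([index[w] for w in s if w in index], dtype=np.int64)
                   for s in sentences]
        encoded = [s for s in encoded if len(s) >= 2]
        if not encoded:
            raise ValueError(
                "corpus has no sentence with >= 2 in-vocabulary tokens; "
                "nothing to form a context window from")

        rng = np.random.default_rng(self.seed)
        V, D = len(vocab), self.dim
        syn0 = rng.uniform(-0.5 / D, 0.5 / D, size=(V, D))
        syn1 = np.zeros((V, D))

        freq = np.array([counts[w] for w in vocab], dtype=np.float64)
        noise = freq ** 0.75
        noise_cdf = np.cumsum(noise / noise.sum())

        total_steps = self.epochs * sum(len(s) for s in encoded)
        step = 0
        k, win = self.negative, self.window
        for _ in range(self.epochs):
            for sent in encoded:
                n = len(sent)
                negs = np.searchsorted(noise_cdf, rng.random((n, k)))
                for t in range(n):
                    alpha = max(self.min_lr,
                                self.lr * (1.0 - step / total_steps))
                    step += 1
                    lo, hi = max(0, t - win), min(n, t + win + 1)
                    ctx = np.concatenate((sent[lo:t], sent[t + 1:hi]))
                    if len(ctx) == 0:
                        continue
                    h = syn0[ctx].mean(axis=0)
                    targets = np.concatenate(([sent[t]], negs[t]))
                    labels = np.zeros(k + 1)
                    labels[0] = 1.0
                    out = syn1[targets]
                    g = (labels - _sigmoid(out @ h)) * alpha
                    err = g @ out
                    syn1[targets] += g[:, None] * h
                    syn0[ctx] += err / len(ctx)

        self.space_ = EmbeddingSpace(words=vocab, matrix=syn0, dim=D)
        self.vocab_counts_ = {w: int(counts[w]) for w in vocab}
        return self


def train_embeddings(sentences, dim=100, window=5, epochs=20, seed=0,
                     **kwargs) -> EmbeddingSpace:
    """Train CBOW embeddings and return the fitted :class:`EmbeddingSpace`."""
    est = CBOWEmbedding(dim=dim, window=window, epochs=epochs, seed=seed,
                        **kwargs)
    return est.fit(sentences).space_
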