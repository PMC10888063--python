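"""Public Opinion Dictionary (POD) construction.

The POD is the set of corpus words judged highly related to the target words
"anxiety" and "depression", each carrying a relevance score alpha in [0, 1].
The pipeline: filter short/irrelevant documents, tokenise, keep frequent
nouns/adjectives of at least two characters, train CBOW embeddings, and score
each candidate by its mean cosine similarity to the targets.

Tokenisation is pluggable. The default tokenizer reads whitespace-delimited
``surface/POS`` tagged tokens (the format the synthetic corpus emits); an
adapter for the jieba Chinese segmenter is provided for real text and imports
jieba lazily.
"""

from __future__ import annotations

from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .embedding import CBOWEmbedding, EmbeddingSpace

__all__ = [
    "TaggedToken", "parse_tagged", "tagged_char_count", "jieba_tokenizer",
    "filter_corpus", "select_vocabulary", "compute_relevance",
    "PODBuilder", "build_pod",
]

DEFAULT_TARGETS = ("anxiety", "depression")
#: POS tags kept by default: nouns and adjectives.
DEFAULT_POS_WHITELIST = ("n", "a")


class TaggedToken(NamedTuple):
    surface: str
    pos: str
    char_len: int


def parse_tagged(text: str, sep: str = "/") -> list:
    """Parse whitespace-delimited ``surface/POS`` tokens.

    A token without a tag separator gets the unknown tag ``"x"``.
    """
    tokens = []
    for chunk in text.split():
        surface, _, pos = chunk.rpartition(sep)
        if not surface:
            surface, pos = pos, "x"
        tokens.append(TaggedToken(surface, pos, len(surface)))
    return tokens


def tagged_char_count(text: str, sep: str = "/") -> int:
    """Character count of a tagged document: total characters of the surfaces."""
    return sum(t.char_len for t in parse_tagged(text, sep=sep))


def jieba_tokenizer() -> Callable[[str], list]:
    """Return a tokenizer backed by the jieba Chinese segmenter.

    Raises ImportError if jieba is not installed; the package itself never
    requires it.
    """
    try:
        from jieba import posseg
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "the jieba tokenizer adapter requires the 'jieba' package; "
            "install it to segment Chinese text") from exc

    def tokenize(text: str) -> list:
        return [TaggedToken(w, flag[:1], len(w)) for w, flag in posseg.cut(text)]

    return tokenize


def filter_corpus(records: pd.DataFrame, min_chars: int = 15,
                  relevance_filter: Optional[Callable[[str], bool]] = None,
                  char_count: Optional[Callable[[str], int]] = None
                  ) -> pd.DataFrame:
    """Drop documents with fewer than ``min_chars`` characters.

    Documents with exactly ``min_chars`` characters are kept ("fewer than"
    is strict). ``relevance_filter``, when given, is an additional per-text
    predicate (the operational stand-in for manual topical screening; the
    default keeps everything). ``char_count`` defaults to the length of the
    whitespace-stripped text. Input row order is preserved.
    """
    if min_chars < 1:
        raise ValueError("min_chars must be >= 1")
    if char_count is None:
        char_count = lambda t: len(t.strip())
    if records.empty:
        return records.copy()
    keep = records["text"].map(lambda t: char_count(t) >= min_chars)
    if relevance_filter is not None:
        keep &= records["text"].map(lambda t: bool(relevance_filter(t)))
    return records.loc[keep].copy()


def select_vocabulary(tokens: Iterable[TaggedToken],
                      pos_whitelist: Sequence[str] = DEFAULT_POS_WHITELIST,
                      min_char_len: int = 2,
                      stopwords: Iterable[str] = (),
                      min_frequency: int = 5) -> dict:
    """Select candidate dictionary words from a tagged token stream.

    A word survives if it occurred at least once with a whitelisted POS tag,
    its surface has at least ``min_char_len`` characters, it is not a
    stopword, and its total corpus frequency is at least ``min_frequency``.
    Returns ``{word: total frequency}``.
    """
    whitelist = set(pos_whitelist)
    if not whitelist:
        raise ValueError("pos_whitelist must not be empty")
    if min_char_len < 1 or min_frequency < 1:
        raise ValueError("min_char_len and min_frequency must be >= 1")
    stopwords = set(stopwords)

    freq: dict = {}
    tagged_ok: set = set()
    for tok in tokens:
        freq[tok.surface] = freq.get(tok.surface, 0) + 1
        if tok.pos in whitelist:
            tagged_ok.add(tok.surface)
    return {w: c for w, c in freq.items()
            if w in tagged_ok and len(w) >= min_char_len
            and w not in stopwords and c >= min_frequency}


def compute_relevance(space: EmbeddingSpace, word: str,
                      targets: Sequence[str] = DEFAULT_TARGETS) -> float:
    """Relevance alpha of ``word``: mean cosine similarity to the targets.

    Clipped to [0, 1] so that the downstream word weights stay nonnegative.
    """
    for tok in (word, *targets):
        if tok not in space:
            raise KeyError(f"token not in embedding vocabulary: {tok!r}")
    sims = [space.cosine(word, t) for t in targets]
    return float(np.clip(np.mean(sims), 0.0, 1.0))


class PODBuilder(BaseEstimator):
    """End-to-end Public Opinion Dictionary builder.

    Chains document filtering, tokenisation, vocabulary selection, CBOW
    training and relevance scoring. The fitted dictionary is a DataFrame
    sorted by alpha descending (ties: frequency descending, then word).

    Parameters largely mirror the individual stages; ``alpha_threshold``
    and ``top_k`` bound the dictionary (both optional, threshold applied
    first). ``tokenizer`` maps a document's text to TaggedTokens; the default
    parses ``surface/POS`` tagged text and documents are sized by the total
    character count of their token surfaces.

    Attributes
    ----------
    pod_ : DataFrame with columns (word, alpha, frequency)
    embedding_ : EmbeddingSpace
    vocabulary_ : dict word -> frequency (pre-threshold candidates)
    n_documents_ : int, documents surviving the corpus filter
    """

    def __init__(self, min_chars=15, pos_whitelist=DEFAULT_POS_WHITELIST,
                 min_char_len=2, stopwords=(), min_frequency=5,
                 dim=100, window=5, epochs=20, min_count=2, negative=5,
                 targets=DEFAULT_TARGETS, alpha_threshold=None, top_k=None,
                 tokenizer=None, relevance_filter=None, seed=0):
        self.min_chars = min_chars
        self.pos_whitelist = pos_whitelist
        self.min_char_len = min_char_len
        self.stopwords = stopwords
        self.min_frequency = min_frequency
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.min_count = min_count
        self.negative = negative
        self.targets = targets
        self.alpha_threshold = alpha_threshold
        self.top_k = top_k
        self.tokenizer = tokenizer
        self.relevance_filter = relevance_filter
        self.seed = seed

    def fit(self, corpus: pd.DataFrame, y=None) -> "PODBuilder":
        tokenizer = self.tokenizer or parse_tagged
        char_count = lambda text: sum(t.char_len for t in tokenizer(text))

        kept = filter_corpus(corpus, min_chars=self.min_chars,
                             relevance_filter=self.relevance_filter,
                             char_count=char_count)
        self.n_documents_ = len(kept)
        doc_tokens = [tokenizer(t) for t in kept["text"]]

        self.vocabulary_ = select_vocabulary(
            (tok for doc in doc_tokens for tok in doc),
            pos_whitelist=self.pos_whitelist, min_char_len=self.min_char_len,
            stopwords=self.stopwords, min_frequency=self.min_frequency)

        sentences = [[tok.surface for tok in doc] for doc in doc_tokens]
        est = CBOWEmbedding(dim=self.dim, window=self.window,
                            epochs=self.epochs, min_count=self.min_count,
                            negative=self.negative, seed=self.seed)
        self.embedding_ = est.fit(sentences).space_

        targets = set(self.targets)
        rows = []
        for word, freq in self.vocabulary_.items():
            if word in targets or word not in self.embedding_:
                continue
            alpha = compute_relevance(self.embedding_, word, self.targets)
            rows.append((word, alpha, freq))
        pod = pd.DataFrame(rows, columns=["word", "alpha", "frequency"])
        pod = pod.sort_values(["alpha", "frequency", "word"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
        if self.alpha_threshold is not None:
            pod = pod[pod["alpha"] >= self.alpha_threshold].reset_index(drop=True)
        if self.top_k is not None:
            pod = pod.head(self.top_k).reset_index(drop=True)
        self.pod_ = pod
        return self


def build_pod(corpus: pd.DataFrame, **params) -> pd.DataFrame:
    """Build a POD from a corpus; see :class:`PODBuilder` for parameters."""
    return PODBuilder(**params).fit(corpus).pod_
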