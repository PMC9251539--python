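"""Text cleaning: tokenization, filtering, stemming, vocabulary building.

The cleaning pipeline, applied in this order:

1. punctuation removal / tokenization — split on any non-alphanumeric run;
2. length filter — drop tokens shorter than ``min_token_length``;
3. digit filter — drop tokens whose digit fraction exceeds the threshold;
4. case folding;
5. stop-word removal (fixed built-in English list);
6. Snowball (Porter2) stemming.

The length and stop-word filters are re-checked after stemming so that every
emitted token satisfies the full contract (a stem can in principle shrink
below the length floor or collide with a stop word).  Documents that end up
empty are kept, flagged, and vectorize to zero rows downstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .config import PreprocessConfig
from .errors import InputError
from .stemming import stem
from .stopwords import STOPWORDS

_TOKEN_SPLIT = re.compile(r"[^0-9A-Za-z]+")
_DIGITS = set("0123456789")


@dataclass
class TokenizedDocument:
    """One document after cleaning: ordered tokens plus its label."""

    doc_id: str
    tokens: list[str]
    label: str | None = None

    @property
    def empty_flag(self) -> bool:
        return len(self.tokens) == 0


@dataclass
class Vocabulary:
    """Lexicographically ordered terms with per-term document frequency."""

    terms: list[str]
    document_frequency: dict[str, int] = field(default_factory=dict)
    n_docs: int = 0

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.document_frequency


def _digit_fraction(token: str) -> float:
    return sum(c in _DIGITS for c in token) / len(token)


def preprocess_document(
    text: str, config: PreprocessConfig | None = None
) -> list[str]:
    """Clean one raw text string into an ordered token list."""
    cfg = config or PreprocessConfig()
    tokens = [t for t in _TOKEN_SPLIT.split(text) if t]
    tokens = [t for t in tokens if len(t) >= cfg.min_token_length]
    tokens = [
        t for t in tokens
        if _digit_fraction(t) <= cfg.digit_fraction_threshold
    ]
    if cfg.lowercase:
        tokens = [t.lower() for t in tokens]
    tokens = [t for t in tokens if t not in STOPWORDS]
    tokens = [stem(t) for t in tokens]
    # re-check the emitted-token contract after stemming
    return [
        t for t in tokens
        if len(t) >= cfg.min_token_length and t not in STOPWORDS
    ]


def tokenize_corpus(
    records: Iterable, config: PreprocessConfig | None = None
) -> list[TokenizedDocument]:
    """Clean every record of a corpus (objects with doc_id/text/label)."""
    cfg = config or PreprocessConfig()
    return [
        TokenizedDocument(
            doc_id=rec.doc_id,
            tokens=preprocess_document(rec.text, cfg),
            label=rec.label,
        )
        for rec in records
    ]


def build_vocabulary(
    docs: Sequence[TokenizedDocument], min_df_fraction: float = 0.01
) -> Vocabulary:
    """Document-frequency-filtered vocabulary over a tokenized corpus.

    A term is retained iff its document frequency is at least
    ``ceil(min_df_fraction * N)`` — i.e. terms appearing in *less than* the
    given fraction of documents are removed.  Each document counts once per
    term.  Term order is lexicographic.
    """
    docs = list(docs)
    if not docs:
        raise InputError("cannot build a vocabulary from an empty corpus")
    n = len(docs)
    df: dict[str, int] = {}
    for doc in docs:
        for term in set(doc.tokens):
            df[term] = df.get(term, 0) + 1
    # ceil with a guard against binary-fraction noise (0.01 * 300 must be 3)
    threshold = max(0, math.ceil(min_df_fraction * n - 1e-9))
    kept = sorted(t for t, c in df.items() if c >= threshold)
    return Vocabulary(
        terms=kept,
        document_frequency={t: df[t] for t in kept},
        n_docs=n,
    )


class TextPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn transformer from raw strings to token lists.

    ``transform`` maps a sequence of raw text strings to a list of token
    lists; it composes with :class:`topictriage.vectorize.RelativeTfVectorizer`
    inside an sklearn :class:`~sklearn.pipeline.Pipeline`.
    """

    def __init__(
        self,
        min_token_length: int = 3,
        digit_fraction_threshold: float = 0.5,
        lowercase: bool = True,
    ):
        self.min_token_length = min_token_length
        self.digit_fraction_threshold = digit_fraction_threshold
        self.lowercase = lowercase

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            min_token_length=self.min_token_length,
            digit_fraction_threshold=self.digit_fraction_threshold,
            lowercase=self.lowercase,
        )

    def fit(self, X: Sequence[str], y=None) -> "TextPreprocessor":
        self._config()  # validate parameters
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> list[list[str]]:
        cfg = self._config()
        return [preprocess_document(text, cfg) for text in X]
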