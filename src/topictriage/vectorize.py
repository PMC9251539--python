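"""Relative term-frequency bag-of-words representation.

Each document vector entry is ``count(term) / len(tokens)`` where the
denominator is the document's *full* post-cleaning token count — including
tokens later dropped by the minimum-document-frequency filter — so row sums
can be below 1.  Empty documents vectorize to all-zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, InputError
from .preprocess import TokenizedDocument, Vocabulary, build_vocabulary


@dataclass
class DocTermMatrix:
    """Documents x vocabulary relative term frequencies with aligned labels."""

    doc_ids: list[str]
    terms: list[str]
    values: np.ndarray  # shape (n_docs, n_terms), float64
    labels: np.ndarray | None = None  # aligned class symbols

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def term_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.doc_ids, columns=self.terms)
        if self.labels is not None:
            frame.insert(len(self.terms), "class", self.labels)
        return frame

    def restrict(self, terms: Sequence[str]) -> "DocTermMatrix":
        """Column-restricted copy, keeping the requested term order."""
        index = self.term_index()
        cols = [index[t] for t in terms]
        return DocTermMatrix(
            doc_ids=list(self.doc_ids),
            terms=list(terms),
            values=self.values[:, cols].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )


def relative_tf(tokens: Sequence[str], vocab_terms: Sequence[str]) -> np.ndarray:
    """Relative term frequencies of one document over a vocabulary."""
    if len(vocab_terms) == 0:
        raise ConfigurationError("vocabulary is empty")
    vec = np.zeros(len(vocab_terms))
    if not tokens:
        return vec
    index = {t: j for j, t in enumerate(vocab_terms)}
    for tok in tokens:
        j = index.get(tok)
        if j is not None:
            vec[j] += 1.0
    return vec / len(tokens)


def build_matrix(
    docs: Sequence[TokenizedDocument],
    vocab: Vocabulary,
    binary: bool = False,
) -> DocTermMatrix:
    """Dense relative-TF matrix, one row per document in input order."""
    docs = list(docs)
    if not docs:
        raise InputError("cannot build a matrix from an empty corpus")
    if len(vocab) == 0:
        raise ConfigurationError("vocabulary is empty")
    values = np.vstack([relative_tf(d.tokens, vocab.terms) for d in docs])
    if binary:
        values = (values > 0).astype(float)
    labels = None
    if all(d.label is not None for d in docs):
        labels = np.asarray([d.label for d in docs], dtype=object)
    return DocTermMatrix(
        doc_ids=[d.doc_id for d in docs],
        terms=list(vocab.terms),
        values=values,
        labels=labels,
    )


def build_matrix_sparse(
    docs: Sequence[TokenizedDocument], vocab: Vocabulary
) -> sparse.csr_matrix:
    """Sparse (CSR) construction of the same matrix; kept as an independent
    implementation so the dense route can be cross-checked against it."""
    if len(vocab) == 0:
        raise ConfigurationError("vocabulary is empty")
    index = {t: j for j, t in enumerate(vocab.terms)}
    data: list[float] = []
    rows: list[int] = []
    cols: list[int] = []
    for i, doc in enumerate(docs):
        if not doc.tokens:
            continue
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        size = len(doc.tokens)
        for j, c in sorted(counts.items()):
            rows.append(i)
            cols.append(j)
            data.append(c / size)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocab.terms))
    )


def count_matrix(
    docs: Sequence[TokenizedDocument], terms: Sequence[str]
) -> sparse.csr_matrix:
    """Integer token-count matrix (LDA input) over a fixed term list."""
    index = {t: j for j, t in enumerate(terms)}
    data: list[int] = []
    rows: list[int] = []
    cols: list[int] = []
    for i, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in sorted(counts.items()):
            rows.append(i)
            cols.append(j)
            data.append(c)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(terms)), dtype=np.int64
    )


class RelativeTfVectorizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style vectorizer over pre-tokenized documents.

    ``fit`` learns the document-frequency-filtered vocabulary from token
    lists; ``transform`` maps token lists to dense relative-TF rows whose
    denominators are each document's own token count.

    Attributes
    ----------
    vocabulary_ : list of str
        Retained terms in lexicographic order.
    document_frequency_ : dict
        Term -> number of fitting documents containing it.
    """

    def __init__(self, min_df_fraction: float = 0.01, binary: bool = False):
        self.min_df_fraction = min_df_fraction
        self.binary = binary

    def fit(self, X: Sequence[list[str]], y=None) -> "RelativeTfVectorizer":
        docs = [
            TokenizedDocument(doc_id=str(i), tokens=list(toks))
            for i, toks in enumerate(X)
        ]
        vocab = build_vocabulary(docs, self.min_df_fraction)
        self.vocabulary_ = list(vocab.terms)
        self.document_frequency_ = dict(vocab.document_frequency)
        self.n_docs_ = vocab.n_docs
        return self

    def transform(self, X: Sequence[list[str]]) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise InputError("RelativeTfVectorizer is not fitted")
        out = np.vstack([relative_tf(toks, self.vocabulary_) for toks in X])
        if self.binary:
            out = (out > 0).astype(float)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.vocabulary_, dtype=object)
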