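"""Topic extraction (component T): LDA over the tokenized training corpus.

Latent Dirichlet Allocation models each document as a mixture over ``k``
topics and each topic as a multinomial over the vocabulary, with symmetric
Dirichlet priors ``alpha`` (document-topic) and ``beta`` (topic-word).
Inference is batch variational Bayes.  A fitted topic is reported as its
``n_topic_words`` highest-probability terms; ties are broken
lexicographically so the word lists are bit-reproducible for a given seed.
Labels are never visible to this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

from .config import LdaConfig
from .errors import ConfigurationError, InputError
from .preprocess import TokenizedDocument
from .vectorize import count_matrix


@dataclass
class Topic:
    """One topic: ordered top words with aligned probabilities."""

    topic_id: str
    words: list[str]
    weights: np.ndarray  # non-increasing, aligned with words


@dataclass
class TopicSet:
    """All fitted topics plus the vocabulary and configuration that made them."""

    topics: list[Topic]
    vocabulary: list[str] = field(default_factory=list)
    config: LdaConfig | None = None

    def __len__(self) -> int:
        return len(self.topics)

    def __iter__(self):
        return iter(self.topics)

    def word_union(self) -> set[str]:
        out: set[str] = set()
        for t in self.topics:
            out.update(t.words)
        return out


def _top_words(
    distribution: np.ndarray, terms: Sequence[str], n: int
) -> tuple[list[str], np.ndarray]:
    """Highest-probability terms; equal probabilities break lexicographically."""
    order = sorted(range(len(terms)), key=lambda j: (-distribution[j], terms[j]))
    top = order[: min(n, len(terms))]
    return [terms[j] for j in top], distribution[top]


def fit_topics(
    docs: Sequence[TokenizedDocument],
    config: LdaConfig | None = None,
    vocabulary: Sequence[str] | None = None,
) -> TopicSet:
    """Fit LDA on the non-empty documents and emit top-word topics.

    Parameters
    ----------
    docs : tokenized documents; empty ones are excluded from fitting.
    config : LDA parameters (k, words per topic, priors, iterations, seed).
    vocabulary : optional fixed term list; defaults to all distinct tokens.
    """
    cfg = config or LdaConfig()
    non_empty = [d for d in docs if d.tokens]
    if not non_empty:
        raise InputError("all documents are empty; cannot fit topics")
    if vocabulary is None:
        terms = sorted({t for d in non_empty for t in d.tokens})
    else:
        terms = list(vocabulary)
    if cfg.n_topics > len(terms):
        raise ConfigurationError(
            f"n_topics={cfg.n_topics} exceeds the {len(terms)} distinct terms"
        )
    counts = count_matrix(non_empty, terms)
    # a fixed vocabulary may zero out some documents entirely
    keep = np.asarray(counts.sum(axis=1)).ravel() > 0
    if not keep.any():
        raise InputError("no document has tokens inside the vocabulary")
    counts = counts[keep]

    lda = LatentDirichletAllocation(
        n_components=cfg.n_topics,
        doc_topic_prior=cfg.alpha,
        topic_word_prior=cfg.beta,
        learning_method="batch",
        max_iter=cfg.iterations,
        evaluate_every=10,
        random_state=cfg.seed,
    )
    lda.fit(counts)
    word_dist = lda.components_ / lda.components_.sum(axis=1, keepdims=True)

    topics = []
    for i in range(cfg.n_topics):
        words, weights = _top_words(word_dist[i], terms, cfg.n_topic_words)
        topics.append(Topic(topic_id=f"topic_{i}", words=words, weights=weights))
    return TopicSet(topics=topics, vocabulary=terms, config=cfg)


class LatentTopicModel:
    """Scikit-learn style estimator around :func:`fit_topics`.

    Parameters mirror :class:`topictriage.config.LdaConfig`.  After ``fit``
    the extracted topics are available as ``topic_set_`` / ``topics_``.
    """

    def __init__(
        self,
        n_topics: int = 20,
        n_topic_words: int = 20,
        alpha: float = 0.1,
        beta: float = 0.1,
        iterations: int = 200,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.n_topic_words = n_topic_words
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_topics": self.n_topics,
            "n_topic_words": self.n_topic_words,
            "alpha": self.alpha,
            "beta": self.beta,
            "iterations": self.iterations,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "LatentTopicModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ConfigurationError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> LdaConfig:
        return LdaConfig(
            n_topics=self.n_topics,
            n_topic_words=self.n_topic_words,
            alpha=self.alpha,
            beta=self.beta,
            iterations=self.iterations,
            seed=self.random_state,
        )

    def fit(self, X: Sequence, y=None) -> "LatentTopicModel":
        """Fit on tokenized documents (or bare token lists)."""
        docs = [
            d if isinstance(d, TokenizedDocument)
            else TokenizedDocument(doc_id=str(i), tokens=list(d))
            for i, d in enumerate(X)
        ]
        self.topic_set_ = fit_topics(docs, self._config())
        self.topics_ = self.topic_set_.topics
        return self
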