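"""End-to-end orchestration: split, clean, vectorize, topics, score, rank,
evaluate accumulation levels, select, fit, predict.

Two entry points:

* :func:`run_pipeline` — the batch workflow: takes a labeled corpus and a
  :class:`~topictriage.config.RunConfig`, writes all output tables, returns
  a :class:`PipelineResult`.
* :class:`BagOfTopicsClassifier` — the same method as a scikit-learn
  classifier over raw text, for composition with sklearn model selection.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .config import RunConfig, ScoringConfig
from .errors import InputError, PipelineError
from .gsm import score_all_topics, stratified_split
from .io import (
    RawCorpus,
    write_accumulation_report,
    write_feature_list,
    write_predictions,
    write_topic_scores,
    write_topic_table,
)
from .modeling import (
    AccumulationReport,
    MetricsRecord,
    ModelArtifact,
    accumulate_vocabulary,
    compute_metrics,
    evaluate_levels,
    fit_final,
    predict_corpus,
)
from .preprocess import build_vocabulary, tokenize_corpus
from .seeds import derive_seed
from .topic_model import TopicSet, fit_topics
from .vectorize import build_matrix

logger = logging.getLogger(__name__)

BEST_F1_TOLERANCE = 0.005


@dataclass
class PipelineResult:
    topic_set: TopicSet
    scores: list
    report: AccumulationReport
    selected_level: int
    selected_words: list[str]
    artifact: ModelArtifact
    config: RunConfig
    holdout_metrics: MetricsRecord | None = None


def select_level(report: AccumulationReport, selected: int | str) -> int:
    """Resolve a level choice; ``"best-f1"`` is the smallest level whose mean
    F1 is within a small tolerance of the maximum (favoring fewer words)."""
    levels = report.levels
    if isinstance(selected, int):
        if selected not in {l.level for l in levels}:
            raise InputError(f"level {selected} not in report")
        return selected
    if selected != "best-f1":
        raise InputError(f"unknown level selector {selected!r}")
    best = max(l.metrics.f1 for l in levels)
    for l in levels:  # levels are sorted ascending
        if l.metrics.f1 >= best - BEST_F1_TOLERANCE:
            return l.level
    return levels[-1].level


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(
    corpus: RawCorpus,
    config: RunConfig | None = None,
    selected_level: int | str = "best-f1",
    levels: Sequence[int] | None = None,
) -> PipelineResult:
    """Run every stage in order; all randomness derives from ``config.seed``."""
    cfg = config or RunConfig()
    corpus.validate()
    if len(corpus.label_values()) != 2:
        raise InputError("pipeline needs a labeled corpus with two classes")

    records = sorted(corpus.records, key=lambda r: r.doc_id)
    labels = np.asarray([r.label for r in records], dtype=object)

    with _stage("holdout-split"):
        if cfg.use_holdout:
            rng = np.random.default_rng(derive_seed(cfg.seed, "holdout", 0))
            train_idx, test_idx = stratified_split(
                labels, cfg.holdout_fraction, rng
            )
            train_records = [records[i] for i in train_idx]
            holdout_records = [records[i] for i in test_idx]
        else:
            train_records = list(records)
            holdout_records = []

    with _stage("preprocess"):
        train_docs = tokenize_corpus(train_records, cfg.preprocess)
        vocab = build_vocabulary(train_docs, cfg.preprocess.min_df_fraction)
        logger.info("[preprocess] vocabulary size %d", len(vocab))

    with _stage("vectorize"):
        matrix = build_matrix(train_docs, vocab)

    with _stage("topics"):
        lda_cfg = replace(cfg.lda, seed=derive_seed(cfg.seed, "lda", 0))
        topic_set = fit_topics(train_docs, lda_cfg, vocabulary=vocab.terms)

    with _stage("scoring"):
        scoring_cfg = replace(
            cfg.scoring, seed=derive_seed(cfg.seed, "scoring", 0)
        )
        scores = score_all_topics(matrix, topic_set, scoring_cfg)
        by_id = {t.topic_id: t for t in topic_set.topics}
        ranking = [by_id[s.topic_id] for s in scores]

    with _stage("evaluate"):
        outer_cfg = replace(cfg.outer, seed=derive_seed(cfg.seed, "outer", 0))
        report = evaluate_levels(
            matrix,
            ranking,
            levels=levels,
            outer=outer_cfg,
            scoring_mode=cfg.scoring_mode,
            scoring_config=scoring_cfg,
            pos_label=cfg.scoring.pos_label,
        )

    with _stage("select"):
        level = select_level(report, selected_level)
        selected_words = [
            w for w in accumulate_vocabulary(ranking, level)
            if w in set(matrix.terms)
        ]

    with _stage("final-model"):
        artifact = fit_final(
            matrix,
            selected_words,
            n_trees=cfg.outer.n_trees,
            seed=derive_seed(cfg.seed, "final", 0),
            pos_label=cfg.scoring.pos_label,
        )

    holdout_metrics = None
    predictions = None
    if holdout_records:
        with _stage("holdout-eval"):
            holdout_corpus = RawCorpus(holdout_records)
            predictions = predict_corpus(
                artifact, holdout_corpus, cfg.preprocess
            )
            holdout_metrics = compute_metrics(
                [r.label for r in holdout_records],
                list(predictions["predicted_label"]),
                scores=list(predictions["score"]),
                pos_label=artifact.pos_label,
            )

    with _stage("write-outputs"):
        out = cfg.output_dir
        os.makedirs(out, exist_ok=True)
        write_topic_table(topic_set, scores, os.path.join(out, "topics.tsv"))
        write_topic_scores(scores, os.path.join(out, "topic_scores.tsv"))
        write_accumulation_report(
            report, os.path.join(out, "accumulation.tsv")
        )
        write_feature_list(
            selected_words, os.path.join(out, "selected_words.txt")
        )
        if predictions is not None:
            write_predictions(
                predictions, os.path.join(out, "holdout_predictions.tsv")
            )

    return PipelineResult(
        topic_set=topic_set,
        scores=scores,
        report=report,
        selected_level=level,
        selected_words=selected_words,
        artifact=artifact,
        config=cfg,
        holdout_metrics=holdout_metrics,
    )


class BagOfTopicsClassifier:
    """Topic-level feature selection plus random forest, as one estimator.

    ``fit(X, y)`` takes raw text strings: it cleans them, learns the
    document-frequency-filtered vocabulary, fits LDA, scores and ranks the
    topics by internal Monte-Carlo CV, accumulates the top
    ``n_topics_selected`` topic vocabularies and trains a random forest on
    those columns.  ``predict``/``predict_proba`` apply the same cleaning
    and vocabulary to new text.

    Follows the scikit-learn estimator protocol (get_params/set_params,
    trailing-underscore fitted attributes), so it drops into pipelines and
    cross-validation utilities.
    """

    def __init__(
        self,
        n_topics: int = 20,
        n_topic_words: int = 20,
        alpha: float = 0.1,
        beta: float = 0.1,
        iterations: int = 200,
        n_topics_selected: int = 5,
        min_df_fraction: float = 0.01,
        inner_reps: int = 10,
        inner_test_fraction: float = 0.1,
        n_trees: int = 100,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.n_topic_words = n_topic_words
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.n_topics_selected = n_topics_selected
        self.min_df_fraction = min_df_fraction
        self.inner_reps = inner_reps
        self.inner_test_fraction = inner_test_fraction
        self.n_trees = n_trees
        self.random_state = random_state

    _PARAM_NAMES = (
        "n_topics", "n_topic_words", "alpha", "beta", "iterations",
        "n_topics_selected", "min_df_fraction", "inner_reps",
        "inner_test_fraction", "n_trees", "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._PARAM_NAMES}

    def set_params(self, **params) -> "BagOfTopicsClassifier":
        for key, value in params.items():
            if key not in self._PARAM_NAMES:
                raise InputError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: Sequence[str], y: Sequence) -> "BagOfTopicsClassifier":
        from .config import LdaConfig, PreprocessConfig
        from .preprocess import TokenizedDocument, preprocess_document

        pre_cfg = PreprocessConfig(min_df_fraction=self.min_df_fraction)

        y = np.asarray([str(v) for v in y], dtype=object)
        if len(y) != len(X):
            raise InputError("X and y differ in length")
        docs = [
            TokenizedDocument(
                doc_id=f"doc_{i:06d}",
                tokens=preprocess_document(text, pre_cfg),
                label=y[i],
            )
            for i, text in enumerate(X)
        ]
        vocab = build_vocabulary(docs, self.min_df_fraction)
        matrix = build_matrix(docs, vocab)
        lda_cfg = LdaConfig(
            n_topics=self.n_topics,
            n_topic_words=self.n_topic_words,
            alpha=self.alpha,
            beta=self.beta,
            iterations=self.iterations,
            seed=derive_seed(self.random_state, "lda", 0),
        )
        topic_set = fit_topics(docs, lda_cfg, vocabulary=vocab.terms)
        scoring_cfg = ScoringConfig(
            inner_reps=self.inner_reps,
            test_fraction=self.inner_test_fraction,
            n_trees=self.n_trees,
            seed=derive_seed(self.random_state, "scoring", 0),
        )
        scores = score_all_topics(matrix, topic_set, scoring_cfg)
        by_id = {t.topic_id: t for t in topic_set.topics}
        self.ranking_ = [by_id[s.topic_id] for s in scores]
        self.scores_ = scores
        r = min(self.n_topics_selected, len(self.ranking_))
        self.selected_words_ = [
            w for w in accumulate_vocabulary(self.ranking_, r)
            if w in set(matrix.terms)
        ]
        self.artifact_ = fit_final(
            matrix,
            self.selected_words_,
            n_trees=self.n_trees,
            seed=derive_seed(self.random_state, "final", 0),
        )
        self.classes_ = self.artifact_.model.classes_
        self._pre_cfg = pre_cfg
        return self

    def _vectors(self, X: Sequence[str]) -> np.ndarray:
        from .preprocess import preprocess_document
        from .vectorize import relative_tf

        return np.vstack(
            [
                relative_tf(
                    preprocess_document(text, self._pre_cfg),
                    self.artifact_.words,
                )
                for text in X
            ]
        )

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return self.artifact_.model.predict(self._vectors(X))

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        return self.artifact_.model.predict_proba(self._vectors(X))

    def score(self, X: Sequence[str], y: Sequence) -> float:
        y = np.asarray([str(v) for v in y], dtype=object)
        return float(np.mean(self.predict(X) == y))
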