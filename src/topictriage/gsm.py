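"""Components G and S: topic sub-datasets and topic scoring/ranking.

Each topic induces a *sub-dataset*: the relative-TF matrix restricted to
that topic's words, with the class labels attached.  A topic's score is the
mean test accuracy of a random forest over repeated stratified Monte-Carlo
train/test splits of its sub-dataset — i.e. how well the topic's words alone
separate the two classes.  Topics are then ranked by score (descending).

Determinism contract: rows are canonically sorted by doc_id before any
sampling, every split and every forest receives a seed derived from the
scoring seed and the repetition index, and the same scoring seed is used for
every topic so identical topics obtain identical scores and the splits are
paired across topics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin

from .config import ScoringConfig
from .errors import EmptyTopicError, InputError, PipelineError, SplitError
from .seeds import derive_seed
from .topic_model import Topic, TopicSet
from .vectorize import DocTermMatrix

logger = logging.getLogger(__name__)


@dataclass
class SubDataset:
    """One topic's columns of the document-term matrix, labels attached."""

    topic_id: str
    terms: list[str]
    doc_ids: list[str]
    X: np.ndarray
    y: np.ndarray


@dataclass
class TopicScore:
    """Mean internal-CV performance of one topic's sub-dataset."""

    topic_id: str
    score: float  # mean accuracy over inner repetitions
    mean_precision: float
    mean_recall: float
    mean_f1: float
    rank: int = 0  # assigned by rank_topics
    confusions: list[tuple[int, int, int, int]] = field(default_factory=list)
    # per-repetition (tp, fp, fn, tn) with respect to the positive class


TopicScoreTable = list[TopicScore]


def resolve_pos_label(y: np.ndarray, pos_label: str | None) -> str:
    """Positive class symbol: configured, else the lexicographically greater."""
    values = sorted({str(v) for v in y})
    if pos_label is not None:
        if str(pos_label) not in values:
            raise InputError(f"pos_label {pos_label!r} not among labels {values}")
        return str(pos_label)
    return values[-1]


def stratified_split(
    y: Sequence[str], test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified Monte-Carlo train/test split over row indices.

    Per class the test part receives ``round(test_fraction * n_c)`` rows,
    clipped to ``[1, n_c - 1]`` so both parts always contain every class.
    Class membership of each split is a pure function of the RNG state.
    """
    y = np.asarray(y, dtype=object)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for value in sorted({str(v) for v in y}):
        members = np.flatnonzero(np.asarray([str(v) == value for v in y]))
        n_c = len(members)
        if n_c < 2:
            raise SplitError(
                f"class {value!r} has {n_c} row(s); need at least 2"
            )
        n_test = int(np.clip(round(test_fraction * n_c), 1, n_c - 1))
        perm = rng.permutation(members)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(test_idx)),
    )


def build_sub_dataset(matrix: DocTermMatrix, topic: Topic) -> SubDataset:
    """Restrict the matrix to one topic's words (topic word order kept)."""
    if matrix.labels is None:
        raise InputError("matrix has no labels; cannot build a sub-dataset")
    present = set(matrix.terms)
    cols = [w for w in topic.words if w in present]
    dropped = [w for w in topic.words if w not in present]
    if not cols:
        raise EmptyTopicError(topic.topic_id)
    if dropped:
        logger.info(
            "[gsm] topic %s: %d word(s) outside vocabulary dropped: %s",
            topic.topic_id, len(dropped), ", ".join(dropped[:5]),
        )
    restricted = matrix.restrict(cols)
    return SubDataset(
        topic_id=topic.topic_id,
        terms=cols,
        doc_ids=list(matrix.doc_ids),
        X=restricted.values,
        y=np.asarray(matrix.labels, dtype=object),
    )


def _confusion(y_true, y_pred, pos: str) -> tuple[int, int, int, int]:
    t = np.asarray([str(v) == pos for v in y_true])
    p = np.asarray([str(v) == pos for v in y_pred])
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return tp, fp, fn, tn


def score_topic(sub: SubDataset, config: ScoringConfig | None = None) -> TopicScore:
    """Score one topic by internal stratified Monte-Carlo cross-validation.

    For each repetition: draw a stratified (1-test_fraction)/test_fraction
    split, fit a random forest on the training part, and record the test
    confusion matrix.  The score is the mean accuracy across repetitions;
    mean precision, recall and F1 are carried as auxiliaries.
    """
    cfg = config or ScoringConfig()
    if len({str(v) for v in sub.y}) < 2:
        raise InputError(
            f"sub-dataset {sub.topic_id!r} has a single class; cannot score"
        )
    pos = resolve_pos_label(sub.y, cfg.pos_label)

    # canonical row order: sort by doc_id so splits are row-order invariant
    order = np.argsort(np.asarray(sub.doc_ids, dtype=object), kind="stable")
    X = sub.X[order]
    y = sub.y[order]

    accs, precs, recs, f1s = [], [], [], []
    confusions = []
    for rep in range(cfg.inner_reps):
        rng = np.random.default_rng(derive_seed(cfg.seed, "score-split", rep))
        train, test = stratified_split(y, cfg.test_fraction, rng)
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            random_state=derive_seed(cfg.seed, "score-forest", rep),
            n_jobs=1,
        )
        forest.fit(X[train], y[train])
        tp, fp, fn, tn = _confusion(y[test], forest.predict(X[test]), pos)
        confusions.append((tp, fp, fn, tn))
        total = tp + fp + fn + tn
        accs.append((tp + tn) / total)
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
        p, r = precs[-1], recs[-1]
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return TopicScore(
        topic_id=sub.topic_id,
        score=float(np.mean(accs)),
        mean_precision=float(np.mean(precs)),
        mean_recall=float(np.mean(recs)),
        mean_f1=float(np.mean(f1s)),
        confusions=confusions,
    )


def score_all_topics(
    matrix: DocTermMatrix,
    topics: TopicSet | Sequence[Topic],
    config: ScoringConfig | None = None,
) -> TopicScoreTable:
    """Score every topic; topics with no word in the vocabulary are skipped."""
    topic_list = list(topics.topics if isinstance(topics, TopicSet) else topics)
    scores: TopicScoreTable = []
    for topic in topic_list:
        try:
            sub = build_sub_dataset(matrix, topic)
        except EmptyTopicError as err:
            logger.warning("[gsm] skipping empty topic: %s", err)
            continue
        scores.append(score_topic(sub, config))
    if not scores:
        raise PipelineError(
            "scoring", InputError("every topic fell outside the vocabulary")
        )
    return rank_topics_inplace(scores)


def _topic_index(topic_id: str) -> tuple[int, str]:
    tail = topic_id.rsplit("_", 1)[-1]
    return (int(tail), topic_id) if tail.isdigit() else (1 << 30, topic_id)


def rank_topics_inplace(scores: TopicScoreTable) -> TopicScoreTable:
    """Assign ranks 1..k by accuracy desc; ties: higher mean F1, lower index."""
    if not scores:
        raise InputError("cannot rank an empty score table")
    ordered = sorted(
        scores,
        key=lambda s: (-s.score, -s.mean_f1, _topic_index(s.topic_id)),
    )
    for rank, s in enumerate(ordered, start=1):
        s.rank = rank
    return ordered


def rank_topics(scores: TopicScoreTable) -> list[str]:
    """Ranked topic-id list (rank 1 first)."""
    return [s.topic_id for s in rank_topics_inplace(list(scores))]


class TopicRankingSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector driven by topic scoring.

    Given the fitted topics (word groups over the matrix columns), ``fit``
    scores and ranks them on ``(X, y)`` and ``transform`` keeps the columns
    belonging to the accumulated vocabulary of the top ``n_topics_selected``
    topics.

    Parameters
    ----------
    topics : sequence of Topic (or a TopicSet).
    feature_names : column names of X, aligned with its columns.
    n_topics_selected : how many top-ranked topics to accumulate.
    """

    def __init__(
        self,
        topics=None,
        feature_names=None,
        n_topics_selected: int = 1,
        inner_reps: int = 10,
        test_fraction: float = 0.1,
        n_trees: int = 100,
        random_state: int = 0,
        pos_label: str | None = None,
    ):
        self.topics = topics
        self.feature_names = feature_names
        self.n_topics_selected = n_topics_selected
        self.inner_reps = inner_reps
        self.test_fraction = test_fraction
        self.n_trees = n_trees
        self.random_state = random_state
        self.pos_label = pos_label

    def fit(self, X, y) -> "TopicRankingSelector":
        from .modeling import accumulate_vocabulary  # local: avoid cycle

        if self.topics is None or self.feature_names is None:
            raise InputError("TopicRankingSelector needs topics and feature_names")
        X = np.asarray(X, dtype=float)
        names = [str(n) for n in self.feature_names]
        if X.shape[1] != len(names):
            raise InputError("feature_names length does not match X columns")
        matrix = DocTermMatrix(
            doc_ids=[str(i) for i in range(X.shape[0])],
            terms=names,
            values=X,
            labels=np.asarray(y, dtype=object),
        )
        cfg = ScoringConfig(
            inner_reps=self.inner_reps,
            test_fraction=self.test_fraction,
            n_trees=self.n_trees,
            seed=self.random_state,
            pos_label=self.pos_label,
        )
        self.scores_ = score_all_topics(matrix, list(self.topics), cfg)
        ranked_ids = [s.topic_id for s in self.scores_]
        by_id = {t.topic_id: t for t in self.topics}
        self.ranking_ = [by_id[i] for i in ranked_ids]
        r = min(self.n_topics_selected, len(self.ranking_))
        selected = accumulate_vocabulary(self.ranking_, r)
        present = set(names)
        self.selected_words_ = [w for w in selected if w in present]
        self.n_features_in_ = X.shape[1]
        self._mask = np.asarray([n in set(self.selected_words_) for n in names])
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self._mask
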