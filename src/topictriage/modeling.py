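"""Component M: top-topic accumulation, outer evaluation and metrics.

The accumulation level ``r`` is the deduplicated union of the word lists of
the top ``r`` ranked topics; a random forest is trained on that vocabulary
and evaluated under outer stratified Monte-Carlo cross-validation (default
100 repetitions of 90/10 splits).  The per-level report carries the mean of
each performance metric over repetitions, the accuracy standard deviation,
and the mean distinct-word count.

All metrics derive from the binary confusion matrix; AUC is the rank-based
probability that a random positive document outscores a random negative one
(ties count one half), with forest class-probability votes as scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .config import OuterEvalConfig, ScoringConfig
from .errors import InputError
from .gsm import (
    SubDataset,
    resolve_pos_label,
    score_topic,
    stratified_split,
)
from .seeds import derive_seed
from .topic_model import Topic
from .vectorize import DocTermMatrix, relative_tf

ARTIFACT_VERSION = 1


@dataclass
class MetricsRecord:
    """Confusion-matrix metrics, all in [0, 1]."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    zero_denominator_flags: tuple[str, ...] = ()


@dataclass
class AccumulationLevel:
    level: int
    n_words: float  # mean distinct-word count over repetitions
    metrics: MetricsRecord  # means over repetitions
    accuracy_std: float = 0.0


@dataclass
class AccumulationReport:
    levels: list[AccumulationLevel]
    ranking: list[str] = field(default_factory=list)  # ranked topic ids


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    scores: Sequence[float] | None = None,
    pos_label: str | None = None,
) -> MetricsRecord:
    """Accuracy, sensitivity, specificity, precision, F1 and AUC.

    ``scores`` are positive-class scores aligned with ``y_true``; without
    them AUC falls back to ranking the hard predictions.  A metric whose
    denominator is zero is reported as 0 and flagged.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise InputError("cannot compute metrics on empty inputs")
    if y_true.shape != y_pred.shape:
        raise InputError("label vectors differ in length")
    if pos_label is not None:
        pos = str(pos_label)  # may legitimately be absent from a small test set
    else:
        pos = resolve_pos_label(np.concatenate([y_true, y_pred]), None)

    t = np.asarray([str(v) == pos for v in y_true])
    p = np.asarray([str(v) == pos for v in y_pred])
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))

    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / (tp + fp + fn + tn)
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        flags.append("f1")
        f1 = 0.0

    if scores is None:
        scores_arr = p.astype(float)
    else:
        scores_arr = np.asarray(scores, dtype=float)
        if scores_arr.shape != y_true.shape:
            raise InputError("scores are not aligned with labels")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        flags.append("auc")
        auc = 0.0
    else:
        ranks = rankdata(scores_arr)  # average ranks: ties count one half
        auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return MetricsRecord(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        auc=float(auc),
        zero_denominator_flags=tuple(flags),
    )


def accumulate_vocabulary(ranked_topics: Sequence[Topic], r: int) -> list[str]:
    """Ordered union of the top-``r`` topics' word lists, duplicates removed."""
    if not 1 <= r <= len(ranked_topics):
        raise InputError(
            f"level r={r} out of range 1..{len(ranked_topics)}"
        )
    seen: set[str] = set()
    words: list[str] = []
    for topic in ranked_topics[:r]:
        for w in topic.words:
            if w not in seen:
                seen.add(w)
                words.append(w)
    return words


def _positive_scores(forest, X, pos: str) -> np.ndarray:
    classes = [str(c) for c in forest.classes_]
    j = classes.index(pos)
    return forest.predict_proba(X)[:, j]


def evaluate_levels(
    matrix: DocTermMatrix,
    ranking: Sequence[Topic],
    levels: Sequence[int] | None = None,
    outer: OuterEvalConfig | None = None,
    scoring_mode: str = "fixed-ranking",
    scoring_config: ScoringConfig | None = None,
    pos_label: str | None = None,
) -> AccumulationReport:
    """Outer stratified MCCV over accumulation levels.

    In ``fixed-ranking`` mode the given ranking is reused for every outer
    repetition; in ``nested`` mode topics are re-scored and re-ranked on each
    repetition's training part (leakage-free, slower).  Within one repetition
    all levels share the same split, so level curves are paired.
    """
    if matrix.labels is None:
        raise InputError("matrix has no labels")
    cfg = outer or OuterEvalConfig()
    ranking = list(ranking)
    if levels is None:
        levels = list(range(1, len(ranking) + 1))
    levels = sorted(set(int(r) for r in levels))
    if not levels or levels[0] < 1 or levels[-1] > len(ranking):
        raise InputError(f"levels {levels} out of range 1..{len(ranking)}")

    order = np.argsort(np.asarray(matrix.doc_ids, dtype=object), kind="stable")
    X_all = matrix.values[order]
    y_all = np.asarray(matrix.labels, dtype=object)[order]
    ids = [matrix.doc_ids[i] for i in order]
    pos = resolve_pos_label(y_all, pos_label)
    term_set = set(matrix.terms)
    term_idx = matrix.term_index()

    per_level: dict[int, dict[str, list[float]]] = {
        r: {k: [] for k in ("accuracy", "sensitivity", "specificity",
                            "precision", "f1", "auc", "n_words")}
        for r in levels
    }

    for rep in range(cfg.reps):
        rng = np.random.default_rng(derive_seed(cfg.seed, "outer-split", rep))
        train, test = stratified_split(y_all, cfg.test_fraction, rng)

        if scoring_mode == "nested":
            from .gsm import score_all_topics  # local import to avoid cycle

            sub_matrix = DocTermMatrix(
                doc_ids=[ids[i] for i in train],
                terms=list(matrix.terms),
                values=X_all[train],
                labels=y_all[train],
            )
            inner_cfg = scoring_config or ScoringConfig(
                seed=derive_seed(cfg.seed, "nested-scoring", rep)
            )
            ranked_scores = score_all_topics(sub_matrix, ranking, inner_cfg)
            by_id = {t.topic_id: t for t in ranking}
            rep_ranking = [by_id[s.topic_id] for s in ranked_scores]
        else:
            rep_ranking = ranking

        for r in levels:
            words = [
                w for w in accumulate_vocabulary(rep_ranking, r)
                if w in term_set
            ]
            if not words:
                raise InputError(f"level {r} has an empty vocabulary")
            cols = [term_idx[w] for w in words]
            forest = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                random_state=derive_seed(cfg.seed, f"outer-forest-{r}", rep),
                n_jobs=1,
            )
            forest.fit(X_all[np.ix_(train, cols)], y_all[train])
            X_test = X_all[np.ix_(test, cols)]
            y_pred = forest.predict(X_test)
            metrics = compute_metrics(
                y_all[test], y_pred,
                scores=_positive_scores(forest, X_test, pos),
                pos_label=pos,
            )
            bucket = per_level[r]
            bucket["accuracy"].append(metrics.accuracy)
            bucket["sensitivity"].append(metrics.sensitivity)
            bucket["specificity"].append(metrics.specificity)
            bucket["precision"].append(metrics.precision)
            bucket["f1"].append(metrics.f1)
            bucket["auc"].append(metrics.auc)
            bucket["n_words"].append(float(len(words)))

    out_levels = []
    for r in levels:
        bucket = per_level[r]
        mean = {k: float(np.mean(v)) for k, v in bucket.items()}
        out_levels.append(
            AccumulationLevel(
                level=r,
                n_words=mean["n_words"],
                metrics=MetricsRecord(
                    accuracy=mean["accuracy"],
                    sensitivity=mean["sensitivity"],
                    specificity=mean["specificity"],
                    precision=mean["precision"],
                    f1=mean["f1"],
                    auc=mean["auc"],
                ),
                accuracy_std=float(np.std(bucket["accuracy"])),
            )
        )
    return AccumulationReport(
        levels=out_levels, ranking=[t.topic_id for t in ranking]
    )


@dataclass
class ModelArtifact:
    """A trained final classifier plus everything needed to apply it."""

    version: int
    words: list[str]
    seed: int
    n_trees: int
    pos_label: str
    model: RandomForestClassifier

    def save(self, path: str) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "ModelArtifact":
        import joblib

        artifact = joblib.load(path)
        if getattr(artifact, "version", None) != ARTIFACT_VERSION:
            raise InputError(
                f"unsupported model artifact version "
                f"{getattr(artifact, 'version', None)!r}"
            )
        return artifact


def fit_final(
    matrix: DocTermMatrix,
    selected_words: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
    pos_label: str | None = None,
) -> ModelArtifact:
    """Train the final random forest on all labeled rows, selected words only."""
    if matrix.labels is None:
        raise InputError("matrix has no labels")
    words = list(selected_words)
    if not words:
        raise InputError("empty word selection")
    missing = [w for w in words if w not in set(matrix.terms)]
    if missing:
        raise InputError(f"selected word(s) outside vocabulary: {missing[:5]}")
    restricted = matrix.restrict(words)
    y = np.asarray(matrix.labels, dtype=object)
    pos = resolve_pos_label(y, pos_label)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=derive_seed(seed, "final-forest", 0),
        n_jobs=1,
    )
    forest.fit(restricted.values, y)
    return ModelArtifact(
        version=ARTIFACT_VERSION,
        words=words,
        seed=seed,
        n_trees=n_trees,
        pos_label=pos,
        model=forest,
    )


def predict_corpus(artifact: ModelArtifact, corpus, preprocess_config=None):
    """Apply a trained artifact to new raw documents.

    Documents are cleaned and vectorized against the artifact's word list
    (each denominator is the document's own token count).  Returns a pandas
    DataFrame with doc_id, predicted_label and the positive-class score.
    """
    import pandas as pd

    from .preprocess import preprocess_document

    rows = []
    vectors = []
    for rec in corpus:
        tokens = preprocess_document(rec.text, preprocess_config)
        vectors.append(relative_tf(tokens, artifact.words))
        rows.append(rec.doc_id)
    X = np.vstack(vectors)
    predictions = artifact.model.predict(X)
    scores = _positive_scores(artifact.model, X, artifact.pos_label)
    return pd.DataFrame(
        {
            "doc_id": rows,
            "predicted_label": [str(v) for v in predictions],
            "score": scores,
        }
    )


def oracle_mean_accuracy(confusions: Sequence[tuple[int, int, int, int]]) -> float:
    """Recompute a topic score from stored per-repetition confusion matrices."""
    accs = [(tp + tn) / (tp + fp + fn + tn) for tp, fp, fn, tn in confusions]
    return float(np.mean(accs))


__all__ = [
    "MetricsRecord", "AccumulationLevel", "AccumulationReport",
    "compute_metrics", "accumulate_vocabulary", "evaluate_levels",
    "ModelArtifact", "fit_final", "predict_corpus", "oracle_mean_accuracy",
    "score_topic", "SubDataset",
]
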