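"""Corpus and table I/O.

Input corpora are delimited text (default tab) with a header row: one
document per row, a unique id column, one or more text columns (concatenated
with a single space, in configured order), and an optional binary label
column.  All output tables are TSV with fixed, documented schemas so they
re-parse deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, ConsistencyError, InputError


@dataclass
class CorpusRecord:
    doc_id: str
    text: str
    label: str | None = None


@dataclass
class RawCorpus:
    """Labeled (or unlabeled) documents; ids unique, at most two label values."""

    records: list[CorpusRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def label_values(self) -> list[str]:
        return sorted({r.label for r in self.records if r.label is not None})

    def validate(self) -> "RawCorpus":
        ids = [r.doc_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate doc_id value(s): {dupes[:5]}")
        observed = self.label_values()
        labelled = [r for r in self.records if r.label is not None]
        if labelled and len(observed) > 2:
            raise InputError(
                f"expected at most 2 label values, found {len(observed)}: "
                f"{observed}"
            )
        return self


def load_corpus(
    path: str,
    id_column: str,
    text_columns: Sequence[str],
    label_column: str | None = None,
    delimiter: str = "\t",
) -> RawCorpus:
    """Read a delimited corpus file into a :class:`RawCorpus`.

    Text columns are concatenated with a single space in the given order;
    rows with empty text are retained (they are flagged downstream).
    """
    frame = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    wanted = [id_column, *text_columns] + (
        [label_column] if label_column else []
    )
    for col in wanted:
        if col not in frame.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path!r} "
                f"(header: {list(frame.columns)})"
            )
    records = []
    for _, row in frame.iterrows():
        text = " ".join(
            part for part in (row[c].strip() for c in text_columns) if part
        )
        records.append(
            CorpusRecord(
                doc_id=row[id_column],
                text=text,
                label=row[label_column] if label_column else None,
            )
        )
    return RawCorpus(records).validate()


def write_corpus(corpus: RawCorpus, path: str, delimiter: str = "\t") -> None:
    """Write a corpus in the same dialect :func:`load_corpus` reads."""
    frame = pd.DataFrame(
        {
            "doc_id": [r.doc_id for r in corpus],
            "text": [r.text for r in corpus],
        }
    )
    if any(r.label is not None for r in corpus):
        frame["label"] = [r.label for r in corpus]
    frame.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def write_topic_table(topic_set, scores, path: str) -> None:
    """One row per topic: topic_id, rank, score, comma-joined words.

    Rows are ordered by rank.  Every scored topic id must exist in the
    topic set.
    """
    known = {t.topic_id for t in topic_set.topics}
    unknown = [s.topic_id for s in scores if s.topic_id not in known]
    if unknown:
        raise ConsistencyError(f"scores reference unknown topic id(s): {unknown}")
    words = {t.topic_id: t.words for t in topic_set.topics}
    rows = [
        {
            "topic_id": s.topic_id,
            "rank": s.rank,
            "score": f"{s.score:.6f}",
            "words": ", ".join(words[s.topic_id]),
        }
        for s in sorted(scores, key=lambda s: s.rank)
    ]
    frame = pd.DataFrame(rows, columns=["topic_id", "rank", "score", "words"])
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_topic_scores(scores, path: str) -> None:
    """Score table: topic_id, rank, score, mean precision/recall/F1."""
    rows = [
        {
            "topic_id": s.topic_id,
            "rank": s.rank,
            "score": f"{s.score:.6f}",
            "mean_precision": f"{s.mean_precision:.6f}",
            "mean_recall": f"{s.mean_recall:.6f}",
            "mean_f1": f"{s.mean_f1:.6f}",
        }
        for s in sorted(scores, key=lambda s: s.rank)
    ]
    frame = pd.DataFrame(
        rows,
        columns=["topic_id", "rank", "score", "mean_precision",
                 "mean_recall", "mean_f1"],
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


ACCUMULATION_COLUMNS = [
    "level", "n_words", "accuracy", "sensitivity", "specificity",
    "f1", "auc", "precision",
]


def write_accumulation_report(report, path: str) -> None:
    """Accumulation report TSV with exactly the documented column set."""
    if not report.levels:
        raise InputError("accumulation report is empty")
    rows = []
    for lvl in report.levels:
        m = lvl.metrics
        values = {
            "accuracy": m.accuracy, "sensitivity": m.sensitivity,
            "specificity": m.specificity, "f1": m.f1, "auc": m.auc,
            "precision": m.precision,
        }
        for name, v in values.items():
            if not 0.0 <= v <= 1.0:
                raise ConsistencyError(
                    f"metric {name}={v} outside [0, 1] at level {lvl.level}"
                )
        rows.append(
            {
                "level": lvl.level,
                "n_words": f"{lvl.n_words:.2f}",
                **{k: f"{v:.3f}" for k, v in values.items()},
            }
        )
    frame = pd.DataFrame(rows, columns=ACCUMULATION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_feature_list(words: Sequence[str], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in words:
            fh.write(f"{w}\n")


def write_predictions(table: pd.DataFrame, path: str) -> None:
    """Prediction table TSV: doc_id, predicted_label, positive-class score."""
    cols = ["doc_id", "predicted_label", "score"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ConsistencyError(f"prediction table missing column(s): {missing}")
    out = table[cols].copy()
    out["score"] = out["score"].map(lambda v: f"{float(v):.6f}")
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
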