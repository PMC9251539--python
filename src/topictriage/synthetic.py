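"""Synthetic labeled corpora with planted topic structure.

The generator emulates a two-class corpus of short documents (think titles
plus abstracts): the vocabulary is partitioned into disjoint planted topic
word blocks plus a pool of noise words, and each document draws its tokens
i.i.d. from a mixture over those blocks.  The two classes share the mixture
except that the *discriminative* blocks carry extra weight in the positive
class — the signal lives at the topic level, not in individual word
identities, which is exactly the structure topic-level feature selection
exploits.  Some documents are emitted empty, mirroring empty-abstract
records in real bibliographic data.

Synthetic words are built to be stem-stable (alternating consonant/vowel
patterns the Snowball stemmer leaves unchanged) and are checked against the
stop-word list, so planted blocks survive preprocessing intact and ground
truth stays aligned with the pipeline vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CorpusRecord, RawCorpus
from .stemming import stem
from .stopwords import STOPWORDS

_CONSONANTS = "bdfgklmnprtz"
_VOWELS = "aeiou"

POSITIVE_LABEL = "pos"
NEGATIVE_LABEL = "neg"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the reference study conditions."""

    n_docs: int = 600
    class_balance: float = 0.5  # proportion positive
    n_planted_topics: int = 6
    words_per_planted_topic: int = 20
    n_noise_words: int = 200
    discriminative_topics: tuple[int, ...] = (0, 1)
    effect_size: float = 0.25  # class difference in discriminative mass
    doc_length_mean: float = 80.0
    doc_length_dispersion: float = 10.0  # negative-binomial size parameter
    empty_doc_fraction: float = 0.02
    noise_weight: float = 0.4  # baseline mixture mass on the noise pool
    concentration: float = 50.0  # Dirichlet concentration of per-doc mixtures
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must lie in (0, 1)")
        if not 0.0 <= self.effect_size < 1.0:
            raise ConfigurationError("effect_size must lie in [0, 1)")
        if any(
            t < 0 or t >= self.n_planted_topics
            for t in self.discriminative_topics
        ):
            raise ConfigurationError(
                "discriminative_topics must index planted topics"
            )
        if self.effect_size >= self.noise_weight:
            raise ConfigurationError(
                "effect_size must be smaller than noise_weight "
                "(the shifted mass comes out of the noise pool)"
            )
        if not 0.0 <= self.empty_doc_fraction < 1.0:
            raise ConfigurationError("empty_doc_fraction must lie in [0, 1)")
        if self.n_docs < 1 or self.n_planted_topics < 1:
            raise ConfigurationError("counts must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted: blocks, class mixtures, per-doc draws."""

    word_blocks: list[list[str]]  # planted topics, pairwise disjoint
    noise_words: list[str]
    class_weights: dict[str, np.ndarray]  # per class, over blocks + noise
    discriminative_topics: tuple[int, ...]
    doc_mixtures: np.ndarray = field(default=None)  # n_docs x (blocks + 1)
    doc_lengths: np.ndarray = field(default=None)


def _make_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Stem-stable, non-stopword, digit-free CVCVC words, unique."""
    words: list[str] = []
    while len(words) < n:
        w = "".join(
            rng.choice(list(_CONSONANTS if i % 2 == 0 else _VOWELS))
            for i in range(5)
        )
        if w in taken or w in STOPWORDS or stem(w) != w:
            continue
        taken.add(w)
        words.append(w)
    return words


def _class_weights(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Mixture weights over (planted blocks..., noise pool) per class.

    Baseline: noise_weight on the noise pool, the rest spread evenly over
    planted blocks.  The positive class moves ``effect_size`` of mass from
    the noise pool onto the discriminative blocks (evenly), so
    non-discriminative blocks have identical expected weight in both classes.
    """
    k = cfg.n_planted_topics
    base = np.full(k + 1, (1.0 - cfg.noise_weight) / k)
    base[-1] = cfg.noise_weight
    pos = base.copy()
    disc = list(cfg.discriminative_topics)
    if disc and cfg.effect_size > 0:
        pos[disc] += cfg.effect_size / len(disc)
        pos[-1] -= cfg.effect_size
    return {NEGATIVE_LABEL: base, POSITIVE_LABEL: pos}


def generate_corpus(
    config: SyntheticConfig | None = None,
) -> tuple[RawCorpus, GroundTruth]:
    """Draw a corpus plus its ground truth from the planted-topic model."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    taken: set[str] = set()
    blocks = [
        _make_words(rng, cfg.words_per_planted_topic, taken)
        for _ in range(cfg.n_planted_topics)
    ]
    noise = _make_words(rng, cfg.n_noise_words, taken)
    pools = blocks + [noise]
    weights = _class_weights(cfg)

    nb_size = cfg.doc_length_dispersion
    nb_mean = max(cfg.doc_length_mean - 1.0, 1e-9)
    nb_p = nb_size / (nb_size + nb_mean)

    records: list[CorpusRecord] = []
    mixtures = np.zeros((cfg.n_docs, cfg.n_planted_topics + 1))
    lengths = np.zeros(cfg.n_docs, dtype=int)
    for i in range(cfg.n_docs):
        label = (
            POSITIVE_LABEL
            if rng.random() < cfg.class_balance
            else NEGATIVE_LABEL
        )
        mixture = rng.dirichlet(cfg.concentration * weights[label])
        mixtures[i] = mixture
        if rng.random() < cfg.empty_doc_fraction:
            records.append(
                CorpusRecord(doc_id=f"doc_{i:05d}", text="", label=label)
            )
            continue
        length = 1 + int(rng.negative_binomial(nb_size, nb_p))
        lengths[i] = length
        components = rng.choice(len(pools), size=length, p=mixture)
        tokens = [
            pools[c][rng.integers(len(pools[c]))] for c in components
        ]
        records.append(
            CorpusRecord(
                doc_id=f"doc_{i:05d}", text=" ".join(tokens), label=label
            )
        )
    truth = GroundTruth(
        word_blocks=blocks,
        noise_words=noise,
        class_weights=weights,
        discriminative_topics=tuple(cfg.discriminative_topics),
        doc_mixtures=mixtures,
        doc_lengths=lengths,
    )
    return RawCorpus(records).validate(), truth


def planted_topics(truth: GroundTruth):
    """The planted word blocks as Topic objects (uniform within-block weights)."""
    from .topic_model import Topic

    return [
        Topic(
            topic_id=f"topic_{i}",
            words=list(block),
            weights=np.full(len(block), 1.0 / len(block)),
        )
        for i, block in enumerate(truth.word_blocks)
    ]


def describe_truth(truth: GroundTruth, path: str) -> None:
    """Write the planted blocks and class mixture weights as TSV."""
    rows = []
    for i, block in enumerate(truth.word_blocks):
        rows.append(
            {
                "kind": "block",
                "name": f"topic_{i}",
                "discriminative": int(i in truth.discriminative_topics),
                "content": " ".join(block),
            }
        )
    rows.append(
        {
            "kind": "block",
            "name": "noise",
            "discriminative": 0,
            "content": " ".join(truth.noise_words),
        }
    )
    for label, w in truth.class_weights.items():
        rows.append(
            {
                "kind": "weights",
                "name": label,
                "discriminative": "",
                "content": " ".join(f"{v:.12f}" for v in w),
            }
        )
    pd.DataFrame(rows, columns=["kind", "name", "discriminative", "content"]) \
        .to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_truth(path: str) -> GroundTruth:
    """Parse a :func:`describe_truth` file back (round-trip for tests)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    blocks: list[list[str]] = []
    noise: list[str] = []
    disc: list[int] = []
    weights: dict[str, np.ndarray] = {}
    for _, row in frame.iterrows():
        if row["kind"] == "block" and row["name"] == "noise":
            noise = row["content"].split()
        elif row["kind"] == "block":
            idx = int(row["name"].rsplit("_", 1)[-1])
            if int(row["discriminative"]):
                disc.append(idx)
            blocks.append(row["content"].split())
        else:
            weights[row["name"]] = np.asarray(
                [float(v) for v in row["content"].split()]
            )
    return GroundTruth(
        word_blocks=blocks,
        noise_words=noise,
        class_weights=weights,
        discriminative_topics=tuple(disc),
    )
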