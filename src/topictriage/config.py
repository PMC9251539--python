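"""Configuration dataclasses for every pipeline stage, plus YAML loading.

Defaults follow the study conditions the pipeline was designed around:
20 LDA topics of 20 words with symmetric Dirichlet priors alpha = beta = 0.1,
stratified 90/10 Monte-Carlo cross-validation repeated 100 times for the
outer evaluation, and a 1% minimum document frequency for the vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class PreprocessConfig:
    """Text-cleaning parameters (see :mod:`topictriage.preprocess`)."""

    min_token_length: int = 3
    digit_fraction_threshold: float = 0.5
    lowercase: bool = True
    min_df_fraction: float = 0.01
    language_filter: bool = False

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ConfigurationError("min_token_length must be >= 1")
        if not 0.0 <= self.min_df_fraction < 1.0:
            raise ConfigurationError("min_df_fraction must lie in [0, 1)")
        if not 0.0 <= self.digit_fraction_threshold <= 1.0:
            raise ConfigurationError("digit_fraction_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class LdaConfig:
    """LDA parameters: k topics, n words per topic, Dirichlet priors."""

    n_topics: int = 20
    n_topic_words: int = 20
    alpha: float = 0.1
    beta: float = 0.1
    iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.n_topic_words < 1:
            raise ConfigurationError("n_topics and n_topic_words must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError("alpha and beta must be positive")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")


@dataclass(frozen=True)
class ScoringConfig:
    """Internal Monte-Carlo CV used to score one topic's sub-dataset."""

    inner_reps: int = 10
    test_fraction: float = 0.1
    n_trees: int = 100
    seed: int = 0
    pos_label: str | None = None  # default: lexicographically greater label

    def __post_init__(self) -> None:
        if self.inner_reps < 1:
            raise ConfigurationError("inner_reps must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


@dataclass(frozen=True)
class OuterEvalConfig:
    """Outer stratified MCCV over accumulation levels (default 100 x 90/10)."""

    reps: int = 100
    test_fraction: float = 0.1
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; every stage seed derives from ``seed``."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lda: LdaConfig = field(default_factory=LdaConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    outer: OuterEvalConfig = field(default_factory=OuterEvalConfig)
    holdout_fraction: float = 0.2
    use_holdout: bool = True
    scoring_mode: str = "fixed-ranking"  # or "nested"
    seed: int = 0
    output_dir: str = "topictriage-output"

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigurationError("holdout_fraction must lie in (0, 1)")
        if self.scoring_mode not in ("fixed-ranking", "nested"):
            raise ConfigurationError(
                "scoring_mode must be 'fixed-ranking' or 'nested'"
            )


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "lda": LdaConfig,
    "scoring": ScoringConfig,
    "outer": OuterEvalConfig,
}


def run_config_from_mapping(mapping: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a flat or nested key-value mapping."""
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = dict(mapping.get(name, {}) or {})
        valid = set(cls.__dataclass_fields__)
        unknown = set(section) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown {name} option(s): {sorted(unknown)}"
            )
        kwargs[name] = cls(**section)
    for key in ("holdout_fraction", "use_holdout", "scoring_mode", "seed",
                "output_dir"):
        if key in mapping:
            kwargs[key] = mapping[key]
    return RunConfig(**kwargs)


def load_run_config(path: str) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config file {path!r} is not a mapping")
    return run_config_from_mapping(data)


def dump_run_config(config: RunConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
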