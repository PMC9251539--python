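import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from topictriage.preprocess import build_vocabulary, tokenize_corpus
from topictriage.synthetic import SyntheticConfig, generate_corpus, planted_topics
from topictriage.vectorize import build_matrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic():
    """Default planted-topic corpus (seed 1) with its ground truth."""
    corpus, truth = generate_corpus(SyntheticConfig(seed=1))
    return corpus, truth


@pytest.fixture(scope="session")
def tokenized(synthetic):
    corpus, _ = synthetic
    return tokenize_corpus(corpus)


@pytest.fixture(scope="session")
def vocabulary(tokenized):
    return build_vocabulary(tokenized, 0.01)


@pytest.fixture(scope="session")
def matrix(tokenized, vocabulary):
    return build_matrix(tokenized, vocabulary)


@pytest.fixture(scope="session")
def planted(synthetic):
    _, truth = synthetic
    return planted_topics(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
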