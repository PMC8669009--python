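import numpy as np
import pytest
from hypothesis import settings

from speechmarkers.lexicon import EmbeddingLexicon
from speechmarkers.synthetic import TopicLexiconSpec, make_topic_lexicon

# property tests must behave identically on every machine and run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_lexicon() -> EmbeddingLexicon:
    """Tiny hand-built lexicon with known geometry (d=3)."""
    vectors = {
        "cat": np.array([1.0, 0.0, 0.0]),
        "dog": np.array([0.8, 0.6, 0.0]),
        "sky": np.array([0.0, 0.0, 1.0]),
        "sun": np.array([0.0, 0.6, 0.8]),
        "anticat": np.array([-1.0, 0.0, 0.0]),
    }
    freqs = {"cat": 0.5, "dog": 0.01, "sky": 0.1, "sun": 0.05, "anticat": 0.5 / 2}
    return EmbeddingLexicon(vectors=vectors, frequencies=freqs, a=1e-3)


@pytest.fixture(scope="session")
def topic_lexicon() -> EmbeddingLexicon:
    """Small generated topical lexicon shared across tests."""
    return make_topic_lexicon(
        TopicLexiconSpec(n_topics=4, words_per_topic=12, dim=10, seed=11)
    )


@pytest.fixture(scope="session")
def topic_lexicon_spec() -> TopicLexiconSpec:
    return TopicLexiconSpec(n_topics=4, words_per_topic=12, dim=10, seed=11)
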