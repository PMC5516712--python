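import pytest
from hypothesis import settings

from ccmer import (
    GeneratorConfig,
    PipelineConfig,
    default_lexicons,
    generate_corpus,
    train_pipeline,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def small_corpus():
    """A compact clean corpus shared by pipeline-level tests."""
    return generate_corpus(GeneratorConfig(n_notes=80, seed=7))


@pytest.fixture(scope="session")
def small_pipeline(small_corpus):
    """One trained cascade reused across tests that need a fitted model."""
    return train_pipeline(small_corpus, PipelineConfig(seed=7))
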