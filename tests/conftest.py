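import pytest
from hypothesis import HealthCheck, settings

from ppikernels.io import blind_and_enumerate, corpus_instances
from ppikernels.synthetic import GeneratorConfig, generate, worked_example

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """Mixed-dialect fixture corpus with <= 30 candidate instances."""
    corpus, _ = generate(
        GeneratorConfig(seed=43, n_documents=9, dialects=("alpha", "beta"))
    )
    return corpus


@pytest.fixture(scope="session")
def fixture_instances(small_corpus):
    instances = corpus_instances(small_corpus)
    assert len(instances) <= 30
    return instances


@pytest.fixture(scope="session")
def worked_instance():
    """The single positive candidate of the hand-encoded example sentence."""
    sentence = worked_example()
    (instance,) = blind_and_enumerate(sentence, "w0")
    return instance
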