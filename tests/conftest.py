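import pytest
from hypothesis import settings

from transcds import synthetic, training

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def strong_bundle():
    """Bundle trained on a moderate strong-signal corpus, shared by tests
    that need a realistic decoder."""
    corpus, _ = synthetic.generate_corpus(
        synthetic.strong_signal_config(seed=101, n=250))
    return training.train(corpus, training.TrainingConfig())


@pytest.fixture(scope="session")
def strong_test_corpus():
    """Held-out complete transcripts from the same conditions."""
    corpus, _ = synthetic.generate_corpus(
        synthetic.strong_signal_config(seed=202, n=60))
    return corpus
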