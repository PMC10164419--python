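import pytest

from vaxsent import CorpusSpec, gen_fixtures, gen_tweets


@pytest.fixture(scope="session")
def separable_corpus():
    """Noise-free synthetic corpus, 100 tweets per ternary class."""
    return gen_tweets(CorpusSpec(n_per_class=100, label_noise=0.0, seed=7))


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic gazetteer + vaccination-center table."""
    return gen_fixtures()
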