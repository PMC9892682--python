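import pytest

from medlex import FixtureSpec, make_toy_corpus, make_toy_lexicon, make_toy_records


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def toy_lexicon(spec):
    return make_toy_lexicon(spec)


@pytest.fixture(scope="session")
def toy_records(toy_lexicon, spec):
    return make_toy_records(toy_lexicon, spec)


@pytest.fixture(scope="session")
def toy_corpus(toy_lexicon, spec):
    return make_toy_corpus(toy_lexicon, spec)
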