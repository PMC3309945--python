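import pytest

from pubmed_expand.fixtures import (
    MI_UI,
    FixtureConfig,
    gen_corpus,
    gen_terminology,
    index_from_fixture,
)
from pubmed_expand.retrieval import LocalProvider, read_corpus_jsonl


@pytest.fixture(scope="session")
def config():
    return FixtureConfig(seed=0)


@pytest.fixture(scope="session")
def term_fixture(config):
    return gen_terminology(config)


@pytest.fixture(scope="session")
def index(term_fixture):
    return index_from_fixture(term_fixture)


@pytest.fixture(scope="session")
def mi(index):
    return index.descriptor(MI_UI)


@pytest.fixture(scope="session")
def corpus_fixture(config, index):
    return gen_corpus(config, index)


@pytest.fixture(scope="session")
def citations(corpus_fixture):
    return read_corpus_jsonl(corpus_fixture.jsonl)


@pytest.fixture(scope="session")
def provider(citations):
    return LocalProvider(citations)
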