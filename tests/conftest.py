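import pytest

from goext.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def bundle():
    return generate_fixtures(seed=1, size="small")


@pytest.fixture(scope="session")
def ontology(bundle):
    return bundle.ontology


@pytest.fixture(scope="session")
def corpus(bundle):
    return bundle.corpus_records()
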