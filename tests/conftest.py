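import pytest
from hypothesis import settings

from phenorag import embedding, fixtures, llm, ontology

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_obo(tmp_path_factory):
    path = tmp_path_factory.mktemp("onto") / "mini.obo"
    fixtures.make_mini_ontology(seed=0, path=path)
    return path


@pytest.fixture(scope="session")
def terms(mini_obo):
    return ontology.parse_ontology(mini_obo, dialect="obo")


@pytest.fixture(scope="session")
def kb(terms):
    return ontology.build_phrase_map(terms, version="hp/mini-fixture-1")


@pytest.fixture(scope="session")
def embedder():
    return embedding.HashingEmbedder(dim=128, seed=7)


@pytest.fixture(scope="session")
def index(kb, embedder):
    return embedding.build_index(embedding.embed_phrases(kb, embedder), kb)


@pytest.fixture(scope="session")
def worked():
    return fixtures.worked_example()


@pytest.fixture()
def make_client():
    def _make(transport, max_retries=1):
        return llm.LlmClient(llm.ModelConfig(max_retries=max_retries), transport)

    return _make
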