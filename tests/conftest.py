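import pytest

from sbokit import (
    FULL_BRANCH,
    FixtureSpec,
    MappingStore,
    build_fixture,
    default_ontology,
    load_default_config,
    load_model,
)


@pytest.fixture(scope="session")
def graph():
    return default_ontology()


@pytest.fixture(scope="session")
def store():
    return MappingStore.default()


@pytest.fixture(scope="session")
def config(graph):
    return load_default_config(graph)


@pytest.fixture(scope="session")
def full_fixture_path(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return build_fixture(FixtureSpec("full_branch", FULL_BRANCH), out)


@pytest.fixture()
def full_doc(full_fixture_path):
    return load_model(full_fixture_path)
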