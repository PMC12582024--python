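import pytest

from phenotext import (
    GeneratorConfig,
    build_synonym_index,
    generate_corpus,
    load_ontology,
    make_fixture_ontology,
)
from phenotext import synthgen
from phenotext.pipeline import PipelineResources

FIXTURE_SEED = 7
FIXTURE_N_TERMS = 30


@pytest.fixture(scope="session")
def fixture_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("onto") / "fixture.obo"
    path.write_text(make_fixture_ontology(FIXTURE_SEED, FIXTURE_N_TERMS), encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def terms(fixture_obo_path):
    return load_ontology(str(fixture_obo_path))


@pytest.fixture(scope="session")
def index(terms):
    return build_synonym_index(terms)


@pytest.fixture(scope="session")
def resources(index):
    return PipelineResources(
        index=index,
        abbreviations=synthgen.build_abbreviation_dictionary(),
        allowlists=synthgen.build_medical_allowlist(),
        denylist=synthgen.build_location_denylist(),
        name_gazetteer=synthgen.build_name_gazetteer(),
    )


@pytest.fixture(scope="session")
def corpus(terms):
    cfg = GeneratorConfig(seed=11, n_reports=50)
    return generate_corpus(cfg, terms)
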