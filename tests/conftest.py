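import pytest

from wsforecast.mutation_catalog import build_spectrum, classify_mutation
from wsforecast.pipeline import fixture_prediction
from wsforecast.synthetic import pf5_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return pf5_fixtures()


@pytest.fixture(scope="session")
def genes(fixtures):
    return fixtures.gene_models


@pytest.fixture(scope="session")
def wt_effects(fixtures):
    return [classify_mutation(r, fixtures.gene_models) for r in fixtures.wt_mutants]


@pytest.fixture(scope="session")
def wt_spectrum(fixtures, wt_effects):
    return build_spectrum(wt_effects, fixtures.gene_models)


@pytest.fixture(scope="session")
def triple_effects(fixtures):
    return [
        classify_mutation(r, fixtures.gene_models)
        for r in fixtures.triple_deletion_mutants
    ]


@pytest.fixture(scope="session")
def prediction():
    """(target_table, params, predicted_spectrum) under the frozen config."""
    return fixture_prediction()
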