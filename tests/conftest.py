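"""Shared fixtures: a small planted-cluster bundle and its layer networks."""

import pytest

from hetlncsim import (
    FixtureParams,
    disease_network,
    expression_network,
    generate_fixture,
    mirna_network,
)
from hetlncsim.disease import DiseaseDAG, disease_similarity_matrix


@pytest.fixture(scope="session")
def small_params():
    return FixtureParams(
        n_lncrnas=12, n_clusters=2, n_mirnas=8, n_diseases=8, n_mrnas=8,
        n_tissues_a=6, n_tissues_b=5, dag_depth=2, dag_branching=2, seed=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return generate_fixture(small_params)


@pytest.fixture(scope="session")
def small_networks(small_bundle):
    b = small_bundle
    dag = DiseaseDAG(b.dag)
    used = sorted(d for d in b.lnc_disease.partners if d in dag)
    ds = disease_similarity_matrix(dag, used)
    return [
        mirna_network(b.lnc_mirna, b.misim, name="mirna"),
        disease_network(b.lnc_disease, ds, name="disease"),
        expression_network(b.expr_a, name="gtex"),
        expression_network(b.expr_b, name="noncode"),
    ]
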