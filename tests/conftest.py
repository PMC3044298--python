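import textwrap

import pytest

from coregnet.core_io import parse_obo, read_ontology
from coregnet.ontology_profiles import map_to_level2
from coregnet.synthetic_fixtures import SyntheticConfig, simulate_bundle

TOY_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: toy

    [Term]
    id: GO:0008150
    name: biological_process
    namespace: biological_process

    [Term]
    id: GO:1000001
    name: term one
    namespace: biological_process
    is_a: GO:0008150 ! biological_process

    [Term]
    id: GO:1000002
    name: term two
    namespace: biological_process
    is_a: GO:0008150 ! biological_process

    [Term]
    id: GO:1000011
    name: term one one
    namespace: biological_process
    is_a: GO:1000001 ! term one

    [Term]
    id: GO:1000012
    name: part of term two
    namespace: biological_process
    relationship: part_of GO:1000002 ! term two
    is_a: GO:1000001 ! term one

    [Term]
    id: GO:1000099
    name: gone
    namespace: biological_process
    is_a: GO:0008150
    is_obsolete: true

    [Term]
    id: GO:3000001
    name: some function
    namespace: molecular_function
    """
)

TOY_ANNOTATIONS = textwrap.dedent(
    """\
    gene\tterm
    g1\tGO:1000001
    g1\tGO:1000002
    g2\tGO:1000001
    g3\tGO:1000011
    g4\tGO:0008150
    g5\tGO:1000012
    """
)


@pytest.fixture
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return str(path)


@pytest.fixture
def toy_annot_path(tmp_path):
    path = tmp_path / "annot.tsv"
    path.write_text(TOY_ANNOTATIONS)
    return str(path)


@pytest.fixture
def toy_dag(toy_obo_path):
    return parse_obo(toy_obo_path)


@pytest.fixture
def toy_ann(toy_obo_path, toy_annot_path):
    dag, raw = read_ontology(toy_obo_path, toy_annot_path, "TSV2")
    return map_to_level2(raw, dag)


@pytest.fixture(scope="session")
def small_config():
    # scaled-down default scenario for fast end-to-end tests
    return SyntheticConfig(
        n_genes=400,
        n_tfs=8,
        n_families=8,
        n_level2_terms=8,
        genes_per_term=40.0,
        n_planted_pairs=4,
        planted_overlap=6,
        background_edge_prob=0.015,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    paths, truth = simulate_bundle(small_config, str(out))
    return {"dir": str(out), "paths": paths, "truth": truth, "config": small_config}
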