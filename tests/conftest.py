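import pytest

import kganno
from kganno.readers import read_expression_csv
from kganno.simulate import demo_world


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """The canonical nine-cluster fixture world (eight pure + one mixture)."""
    return demo_world(seed=1)


@pytest.fixture(scope="session")
def world_inputs(world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("world_inputs")
    return world.write_inputs(outdir)


@pytest.fixture(scope="session")
def base_kg(world_inputs):
    kg = kganno.load_ontology(world_inputs["ontology"])
    kganno.load_gene_sets(world_inputs["gene_sets"], into=kg)
    return kg


@pytest.fixture(scope="session")
def dataset_kg(base_kg, world_inputs):
    expr = read_expression_csv(world_inputs["expression"])
    return kganno.build_dataset_kg(base_kg, expr)


@pytest.fixture(scope="session")
def clusters(world):
    return [
        kganno.ClusterInput(c["cluster_id"], c["markers"], mixed_hint=c["mixed"])
        for c in world.clusters
    ]
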