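import numpy as np
import pytest

from coexcons import (
    GeneratorConfig,
    HomologyTable,
    build_coexpression_map,
    generate_world,
)
from coexcons.synthetic_data import generate_map_pair, random_map


@pytest.fixture(scope="session")
def tiny_config():
    return GeneratorConfig(
        n_genes_a=150,
        n_genes_b=150,
        n_datasets=5,
        n_conditions=6,
        n_modules=5,
        module_size=25,
        planted_set_size=12,
        n_null_sets=5,
        n_planted_per_type=2,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return generate_world(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_maps(tiny_world):
    map_a = build_coexpression_map(tiny_world.datasets_a, species="a")
    map_b = build_coexpression_map(tiny_world.datasets_b, species="b")
    return map_a, map_b


@pytest.fixture()
def toy_map_pair():
    return generate_map_pair(n_genes=40, n_modules=4, z=0.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_identity_homology(genes_a, genes_b):
    """one2one table pairing genes positionally (toy fixture helper)."""
    pairs = list(zip(genes_a, genes_b))
    n = len(pairs)
    return HomologyTable(
        pairs=pairs,
        relationship=["one2one"] * n,
        dn=np.full(n, 0.1),
        ds=np.full(n, 1.0),
        universe_a=set(genes_a),
        universe_b=set(genes_b),
    )


@pytest.fixture()
def random_toy_maps():
    return random_map(30, seed=5, species="ta"), random_map(30, seed=6, species="tb")
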