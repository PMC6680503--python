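import random

import pytest

from netenhance import CosineEdge, NodeRecord, build_network
from netenhance.fixtures import generate_bundle, write_six_node_demo


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seed-7 toy bundle plus its ground-truth manifest."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = generate_bundle(out, seed=7)
    return out, manifest


@pytest.fixture(scope="session")
def six_node_demo(tmp_path_factory):
    """The worked six-node family (plus one singleton) as input files."""
    out = tmp_path_factory.mktemp("demo")
    return write_six_node_demo(out)


def random_network(rng: random.Random, n_max: int = 12, p_edge: float = 0.25):
    """Small random cosine graph for oracle-equivalence checks."""
    n = rng.randint(1, n_max)
    ids = rng.sample(range(1, 100), n)
    nodes = [NodeRecord(cluster_id=c) for c in ids]
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if rng.random() < p_edge:
                edges.append(CosineEdge(id_a=a, id_b=b,
                                        cosine=round(rng.uniform(0.6, 1.0), 3)))
    return nodes, edges


@pytest.fixture
def toy_network():
    """6 nodes: one 4-chain, one pair -> families sized 4 and 2."""
    nodes = [NodeRecord(cluster_id=c, precursor_mz=100.0 + c) for c in range(1, 7)]
    edges = [
        CosineEdge(1, 2, 0.9), CosineEdge(2, 3, 0.8), CosineEdge(3, 4, 0.7),
        CosineEdge(5, 6, 0.95),
    ]
    return build_network(nodes, edges)
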