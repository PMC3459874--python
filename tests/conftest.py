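import pytest

from tsppi.evaluation import NetworkVariant, loocv
from tsppi.networks import ReweightConfig, edge_reweight
from tsppi.synthetic import SyntheticConfig, generate, planted_benchmark


@pytest.fixture(scope="session")
def small_bundle():
    """A compact generated bundle for fast module-level tests."""
    cfg = SyntheticConfig(
        seed=11, n_genes=400, n_tissues=6, n_diseases=24,
        family_size=4, chromosome_size=200, attachment_m=2,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def decoy_bundle():
    """The planted decoy benchmark at its default study conditions."""
    return planted_benchmark(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def decoy_tissue_nets(decoy_bundle):
    b = decoy_bundle
    return {
        t: edge_reweight(b.network, b.profiles.expressed_in(t), ReweightConfig(0.1))
        for t in b.tissues
    }


@pytest.fixture(scope="session")
def decoy_cases(decoy_bundle, decoy_tissue_nets):
    """LOOCV cases of the decoy benchmark: generic vs TS-ERW (rw=0.1)."""
    b = decoy_bundle
    variants = [
        NetworkVariant(label="generic", network=b.network),
        NetworkVariant(label="ts-erw", by_tissue=decoy_tissue_nets),
    ]
    return loocv(
        b.associations, variants,
        sim=b.similarity, catalog=b.catalog, interval_network=b.network,
        assign=b.assignment, profiles=b.profiles,
        mas_threshold=40.0, expressed_only=True,
    )


def random_weighted_network(rng, n, m):
    """Random simple weighted graph over n nodes (all nodes in the node set)."""
    import networkx as nx
    from tsppi.core import WeightedNetwork

    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    net = WeightedNetwork()
    for u, v in g.edges():
        net.add_edge(u, v, float(rng.uniform(0.05, 1.0)))
    net._nodes.update(range(n))
    return net
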