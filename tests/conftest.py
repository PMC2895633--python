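import numpy as np
import pytest

from subnetusage.datasets import example_network
from subnetusage.subnets import enumerate_subnets
from subnetusage.synthetic import SyntheticSpec, generate_trn


@pytest.fixture(scope="session")
def fig_net():
    """The 10-node illustration network (three subnets, one FFL)."""
    return example_network()


@pytest.fixture(scope="session")
def synth_trn():
    """Default desk-scale hierarchical synthetic TRN with planted motifs."""
    spec = SyntheticSpec(seed=7)
    net, subnets = generate_trn(spec)
    return spec, net, subnets


@pytest.fixture(scope="session")
def flat_trn():
    """Flat (regulon-like) synthetic TRN: quasi-disjoint single-input subnets,
    the configuration used for planted-recovery experiments."""
    spec = SyntheticSpec(hierarchy_depth=1, ffl_count=0, two_cycle_count=0, seed=7)
    net, subnets = generate_trn(spec)
    return spec, net, subnets


@pytest.fixture(scope="session")
def genome_flat_trn():
    """Flat synthetic TRN at the real genome's scale (~1540 nodes), used where
    enrichment power depends on background size (sRNA recovery)."""
    spec = SyntheticSpec(
        n_targets=1500, hierarchy_depth=1, ffl_count=0, two_cycle_count=0, seed=7
    )
    net, subnets = generate_trn(spec)
    return spec, net, subnets


@pytest.fixture(scope="session")
def ffl_rich_trn():
    """Hierarchical TRN whose planted feed-forward excess dominates the
    chance closures implied by its degree sequence (tamer out-degree tail)."""
    spec = SyntheticSpec(out_degree_exponent=3.0, ffl_count=50, seed=7)
    net, subnets = generate_trn(spec)
    return spec, net, subnets


def random_digraph(rng: np.random.Generator, n_nodes: int, p: float):
    """Small Erdős–Rényi-style digraph as a RegulatoryNetwork (no self-loops)."""
    from subnetusage.network import InteractionRecord, build_network

    names = [f"n{i}" for i in range(n_nodes)]
    records = [
        InteractionRecord(names[i], names[j])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and rng.random() < p
    ]
    net = build_network(records, dimer_map={}, phantom_genes=())
    net.graph.add_nodes_from(names)
    return net
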