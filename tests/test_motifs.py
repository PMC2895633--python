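"""Triad census, canonical ids, randomization z-scores and FFL null models."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from subnetusage.motifs import (
    FFL_ID,
    canonical_triad_id,
    cluster_induced_subgraph,
    connected_triads,
    count_ffl,
    degree_preserving_randomize,
    induced_subgraph,
    motif_zscores,
    triad_census,
)
from subnetusage.network import InteractionRecord, build_network
from subnetusage.subnets import compute_subnet

from conftest import random_digraph


def _net(*pairs):
    return build_network([InteractionRecord(u, v) for u, v in pairs], dimer_map={})


class TestCanonicalId:
    def test_feed_forward_loop_is_38(self):
        # c regulates a and b; b regulates a
        adj = [[0, 0, 0], [1, 0, 0], [1, 1, 0]]
        assert canonical_triad_id(adj) == 38

    def test_id_110_decodes_to_expected_edge_set(self):
        # 0b001101110: edges 1→3, 2→1, 2→3, 3→1, 3→2
        adj = [[0, 0, 1], [1, 0, 1], [1, 1, 0]]
        assert canonical_triad_id(adj) == 110

    def test_chain_id_equals_brute_force_minimum(self):
        adj = [[0, 1, 0], [0, 0, 1], [0, 0, 0]]  # a→b→c

        def encode(a):
            code = 0
            for i in range(3):
                for j in range(3):
                    code = (code << 1) | a[i][j]
            return code

        perms = []
        for p in itertools.permutations(range(3)):
            perms.append(encode([[adj[p[i]][p[j]] for j in range(3)] for i in range(3)]))
        assert canonical_triad_id(adj) == min(perms)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            adj = (rng.random((3, 3)) < 0.5).astype(int)
            np.fill_diagonal(adj, 0)
            try:
                cid = canonical_triad_id(adj)
            except ValueError:
                continue
            p = rng.permutation(3)
            relabeled = adj[np.ix_(p, p)]
            assert canonical_triad_id(relabeled) == cid

    def test_disconnected_triad_rejected(self):
        with pytest.raises(ValueError):
            canonical_triad_id([[0, 1, 0], [0, 0, 0], [0, 0, 0]])


def _census_oracle(net):
    """Brute force over all node triples."""
    nodes = sorted(net.nodes)
    counts = Counter()
    for trio in itertools.combinations(nodes, 3):
        adj = [[1 if net.has_edge(u, v) else 0 for v in trio] for u in trio]
        try:
            counts[canonical_triad_id(adj)] += 1
        except ValueError:
            continue
    return counts


class TestCensus:
    def test_single_ffl(self):
        c = triad_census(_net(("x", "y"), ("x", "z"), ("y", "z")))
        assert dict(c.counts) == {FFL_ID: 1}
        assert c.total_connected_triples == 1

    def test_example_network_has_one_ffl_triad(self, fig_net):
        c = triad_census(fig_net)
        assert c.counts[FFL_ID] == 1
        # the FFL triple is exactly {a, b, c}
        ffl = [trio for trio, cid in connected_triads(fig_net) if cid == FFL_ID]
        assert ffl == [("a", "b", "c")]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_digraph(rng, int(rng.integers(6, 13)), 0.25)
        c = triad_census(net)
        assert c.counts == _census_oracle(net)
        assert sum(c.counts.values()) == c.total_connected_triples

    def test_matches_networkx_triadic_census(self):
        # independent library cross-check on a fixed random graph
        import networkx as nx

        rng = np.random.default_rng(5)
        net = random_digraph(rng, 12, 0.2)
        nx_census = nx.triadic_census(net.graph)
        disconnected = {"003", "012", "102"}
        n_connected = sum(v for k, v in nx_census.items() if k not in disconnected)
        assert triad_census(net).total_connected_triples == n_connected


class TestRandomization:
    def test_degree_sequences_preserved(self, synth_trn):
        _, net, _ = synth_trn
        rnet = degree_preserving_randomize(net, n_swap_multiplier=5, seed=3)
        assert dict(rnet.graph.out_degree()) == dict(net.graph.out_degree())
        assert dict(rnet.graph.in_degree()) == dict(net.graph.in_degree())
        assert rnet.n_links == net.n_links
        assert all(u != v for u, v in rnet.edges)

    def test_two_edge_chain_unchanged(self):
        net = _net(("a", "b"), ("b", "c"))
        rnet = degree_preserving_randomize(net, n_swap_multiplier=50, seed=0)
        assert rnet.edges == net.edges

    def test_seed_reproducibility(self, synth_trn):
        _, net, _ = synth_trn
        r1 = degree_preserving_randomize(net, n_swap_multiplier=5, seed=11)
        r2 = degree_preserving_randomize(net, n_swap_multiplier=5, seed=11)
        assert r1.edges == r2.edges

    def test_randomization_destroys_planted_ffl_excess(self, ffl_rich_trn):
        _, net, _ = ffl_rich_trn
        original = count_ffl(net)
        counts = [
            count_ffl(degree_preserving_randomize(net, n_swap_multiplier=10, seed=s))
            for s in range(20)
        ]
        assert float(np.mean(counts)) < original


class TestZScores:
    def test_null_self_consistency_on_random_graph(self):
        rng = np.random.default_rng(1)
        net = random_digraph(rng, 30, 0.06)
        sig = motif_zscores(net, n_random=100, n_swap_multiplier=10, seed=2)
        finite = [v for v in sig.z.values() if math.isfinite(v)]
        # no planted structure: the large majority of triad types are unremarkable
        assert np.mean([abs(v) <= 3 for v in finite]) >= 0.8

    def test_planted_ffl_network_has_top_positive_ffl_z(self, ffl_rich_trn):
        _, net, _ = ffl_rich_trn
        sig = motif_zscores(net, n_random=50, n_swap_multiplier=10, seed=4)
        finite = {k: v for k, v in sig.z.items() if math.isfinite(v)}
        assert max(finite, key=finite.get) == FFL_ID
        assert finite[FFL_ID] > 0

    def test_tsp_unit_norm(self, synth_trn):
        _, net, _ = synth_trn
        sig = motif_zscores(net, n_random=20, n_swap_multiplier=5, seed=5)
        norm = math.sqrt(sum(v * v for v in sig.tsp.values()))
        assert norm == pytest.approx(1.0, abs=1e-12)


class TestInducedSubgraphs:
    def test_full_induction_includes_shortcut_edges(self):
        # edge e→g exists between members of b's subnet but is not on a path from b
        net = _net(("b", "e"), ("b", "g"), ("e", "g"))
        s = compute_subnet(net, "b")
        ind = induced_subgraph(net, s.members)
        assert ("e", "g") in ind.edges

    def test_union_of_overlapping_subnets(self, fig_net):
        sb = compute_subnet(fig_net, "b")
        sd = compute_subnet(fig_net, "d")
        ind = cluster_induced_subgraph(fig_net, [sb, sd])
        assert ind.nodes == sb.members | sd.members
        assert ind.n_nodes == 9  # all but root a; shared node g appears once
        assert ind.n_links == 8

    def test_empty_cluster_gives_empty_graph(self, fig_net):
        ind = cluster_induced_subgraph(fig_net, [])
        assert ind.n_nodes == 0 and ind.n_links == 0


def test_ffl_count_consistent_with_ordered_triple_definition(synth_trn):
    _, net, _ = synth_trn
    g = net.graph
    n_exact = 0
    for trio, cid in connected_triads(net):
        if cid == FFL_ID:
            n_exact += 1
    # ordered-triple count of x→y, y→z, x→z patterns with no other edges among them
    ordered = 0
    for x, y in g.edges:
        for z in g.successors(y):
            if z != x and g.has_edge(x, z):
                extra = (
                    g.has_edge(y, x) or g.has_edge(z, y) or g.has_edge(z, x)
                )
                if not extra:
                    ordered += 1
    assert n_exact == ordered
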