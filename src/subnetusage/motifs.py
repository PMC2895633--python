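"""Three-node motif analysis: triad census, randomization z-scores, triad
significance profiles, cluster-induced subgraphs and feed-forward-loop null
models.

A *triad* is the subgraph induced by an unordered node triple; only weakly
connected triads are counted.  Each triad's adjacency matrix is encoded
row-major as a 9-bit integer (bit weight 2⁸ for entry [0][0] down to 2⁰ for
[2][2], diagonal zero) and the canonical id is the minimum encoding over the
six node relabelings — the feed-forward loop gets id 38 under this
convention.  Motif z-scores compare real counts with those of
degree-preserving edge-swap randomizations; the triad significance profile
(TSP) is the z-vector normalized to unit length, comparable across networks
of different size.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .network import RegulatoryNetwork
from .subnets import Subnet

__all__ = [
    "FFL_ID",
    "TriadCensus",
    "MotifSignificance",
    "canonical_triad_id",
    "triad_census",
    "connected_triads",
    "degree_preserving_randomize",
    "motif_zscores",
    "cluster_induced_subgraph",
    "ffl_null_models",
    "FflNullModelResult",
]

#: Canonical id of the feed-forward loop (X→Y, X→Z, Y→Z).
FFL_ID = 38

_PERMS = list(itertools.permutations(range(3)))


def _encode(adj: Sequence[Sequence[int]]) -> int:
    code = 0
    for i in range(3):
        for j in range(3):
            code = (code << 1) | (1 if adj[i][j] else 0)
    return code


def _min_encoding(adj: Sequence[Sequence[int]]) -> int:
    best = 1 << 9
    for p in _PERMS:
        code = 0
        for i in range(3):
            for j in range(3):
                code = (code << 1) | (1 if adj[p[i]][p[j]] else 0)
        best = min(best, code)
    return best


def _weakly_connected(adj: Sequence[Sequence[int]]) -> bool:
    und = [[adj[i][j] or adj[j][i] for j in range(3)] for i in range(3)]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(3):
            if und[i][j] and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == 3


def canonical_triad_id(adjacency: Sequence[Sequence[int]]) -> int:
    """Canonical id of a 3-node triad (minimum 9-bit encoding over relabelings).

    The adjacency matrix must have a zero diagonal, at least one edge, and be
    weakly connected.
    """
    adj = [[1 if adjacency[i][j] else 0 for j in range(3)] for i in range(3)]
    if any(adj[i][i] for i in range(3)):
        raise ValueError("triad adjacency must have a zero diagonal")
    if not any(adj[i][j] for i in range(3) for j in range(3)):
        raise ValueError("triad has no edges")
    if not _weakly_connected(adj):
        raise ValueError("triad is not weakly connected")
    return _min_encoding(adj)


def _build_canonical_table() -> list[int | None]:
    """Map the 6 off-diagonal bits ((0,1),(0,2),(1,0),(1,2),(2,0),(2,1)) to a
    canonical id, or None for disconnected/empty triads."""
    table: list[int | None] = []
    offdiag = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    for code in range(64):
        adj = [[0] * 3 for _ in range(3)]
        for bit, (i, j) in enumerate(offdiag):
            if code & (1 << (5 - bit)):
                adj[i][j] = 1
        if not any(adj[i][j] for i in range(3) for j in range(3)) or not _weakly_connected(adj):
            table.append(None)
        else:
            table.append(_min_encoding(adj))
    return table


_CANONICAL_TABLE = _build_canonical_table()


@dataclass
class TriadCensus:
    counts: Counter
    total_connected_triples: int


def _adjacency_sets(net: RegulatoryNetwork) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    succ: dict[str, set[str]] = {n: set() for n in net.graph.nodes}
    und: dict[str, set[str]] = {n: set() for n in net.graph.nodes}
    for u, v in net.graph.edges:
        succ[u].add(v)
        und[u].add(v)
        und[v].add(u)
    return succ, und


def connected_triads(net: RegulatoryNetwork) -> Iterator[tuple[tuple[str, str, str], int]]:
    """Yield every weakly connected node triple with its canonical triad id.

    Triples are enumerated from pairs of undirected neighbours, so the cost
    scales with Σ_v C(deg(v), 2) rather than C(n, 3).  Self-loops are ignored
    (they live outside the analysis graph).
    """
    succ, und = _adjacency_sets(net)
    offdiag = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    # every connected triple has at least one "center" adjacent to both other
    # nodes; a non-triangle has exactly one, a triangle has three.  Emitting
    # a triple only from its unique center (or, for triangles, the smallest
    # center) counts each triple exactly once without a dedup set.
    for u in net.graph.nodes:
        nbrs = sorted(und[u])
        for v, w in itertools.combinations(nbrs, 2):
            if w in und[v] and not (u < v and u < w):
                continue  # triangle: only its smallest node emits
            trio = tuple(sorted((u, v, w)))
            code = 0
            for i, j in offdiag:
                code = (code << 1) | (1 if trio[j] in succ[trio[i]] else 0)
            cid = _CANONICAL_TABLE[code]
            if cid is not None:
                yield trio, cid


def triad_census(net: RegulatoryNetwork) -> TriadCensus:
    """Count weakly connected induced triads by canonical id."""
    counts: Counter = Counter()
    total = 0
    for _, cid in connected_triads(net):
        counts[cid] += 1
        total += 1
    return TriadCensus(counts=counts, total_connected_triples=total)


def count_ffl(net: RegulatoryNetwork) -> int:
    """Number of induced feed-forward-loop triads (canonical id 38)."""
    return triad_census(net).counts.get(FFL_ID, 0)


def degree_preserving_randomize(
    net: RegulatoryNetwork, n_swap_multiplier: int = 100, seed: int = 0
) -> RegulatoryNetwork:
    """Randomize by repeated pairwise edge swaps preserving all degrees.

    ``n_swap_multiplier × |edges|`` attempts are made; an attempt picks two
    distinct edges (a→b, c→d) and rewires them to (a→d, c→b) unless that
    would create a self-loop or a duplicate edge.  In- and out-degrees are
    preserved exactly; failed attempts are skipped.
    """
    rng = np.random.default_rng(seed)
    edges = list(net.graph.edges)
    edge_set = set(edges)
    m = len(edges)
    if m >= 2:
        for _ in range(n_swap_multiplier * m):
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if a == d or c == b or b == d or a == c:
                continue
            if (a, d) in edge_set or (c, b) in edge_set:
                continue
            edge_set.remove((a, b))
            edge_set.remove((c, d))
            edge_set.add((a, d))
            edge_set.add((c, b))
            edges[i] = (a, d)
            edges[j] = (c, b)
    out = RegulatoryNetwork()
    out.graph.add_nodes_from(net.graph.nodes)
    out.graph.add_edges_from(edges)
    out.self_loops = set(net.self_loops)
    return out


@dataclass
class MotifSignificance:
    ids: list[int]
    n_real: dict[int, int]
    null_mean: dict[int, float]
    null_sd: dict[int, float]
    z: dict[int, float]  # NaN where the null sd is 0 but counts differ
    tsp: dict[int, float]
    n_random: int
    flagged: set[int] = field(default_factory=set)


def motif_zscores(
    net: RegulatoryNetwork,
    n_random: int = 1000,
    n_swap_multiplier: int = 100,
    seed: int = 0,
) -> MotifSignificance:
    """Triad z-scores against degree-preserving randomizations.

    For every canonical id observed in the real network or any randomization:
    ``z = (n_real − null_mean) / null_sd``.  Ids with zero null spread are
    flagged: z is 0 when the real count equals the (constant) null count and
    NaN otherwise.  The TSP is the z-vector over ids with defined z, scaled
    to unit Euclidean norm.
    """
    real = triad_census(net).counts
    rng = np.random.default_rng(seed)
    null_counts: list[Counter] = []
    for _ in range(n_random):
        rnet = degree_preserving_randomize(
            net, n_swap_multiplier=n_swap_multiplier, seed=int(rng.integers(2**31))
        )
        null_counts.append(triad_census(rnet).counts)
    ids = sorted(set(real) | set().union(*null_counts) if null_counts else set(real))
    n_real, null_mean, null_sd, z = {}, {}, {}, {}
    flagged: set[int] = set()
    for cid in ids:
        obs = real.get(cid, 0)
        nulls = np.array([c.get(cid, 0) for c in null_counts], dtype=float)
        mu = float(nulls.mean()) if nulls.size else 0.0
        sd = float(nulls.std(ddof=0)) if nulls.size else 0.0
        n_real[cid] = obs
        null_mean[cid] = mu
        null_sd[cid] = sd
        if sd > 0:
            z[cid] = (obs - mu) / sd
        else:
            flagged.add(cid)
            z[cid] = 0.0 if obs == mu else math.nan
    finite = {cid: v for cid, v in z.items() if math.isfinite(v)}
    norm = math.sqrt(sum(v * v for v in finite.values()))
    tsp = {cid: (v / norm if norm > 0 else 0.0) for cid, v in finite.items()}
    return MotifSignificance(
        ids=ids, n_real=n_real, null_mean=null_mean, null_sd=null_sd,
        z=z, tsp=tsp, n_random=n_random, flagged=flagged,
    )


def induced_subgraph(net: RegulatoryNetwork, nodes: Iterable[str]) -> RegulatoryNetwork:
    """Subgraph induced by a node set (all edges with both endpoints inside)."""
    nodes = set(nodes) & net.nodes
    out = RegulatoryNetwork()
    out.graph = net.graph.subgraph(nodes).copy()
    out.self_loops = net.self_loops & nodes
    return out


def cluster_induced_subgraph(
    net: RegulatoryNetwork, cluster_subnets: Sequence[Subnet]
) -> RegulatoryNetwork:
    """Subgraph induced by the union of a cluster's subnet members.

    Inducing one subgraph per cluster (rather than per subnet) ensures every
    motif instance is counted once, even when subnets overlap.
    """
    union: set[str] = set()
    for s in cluster_subnets:
        union |= s.members
    return induced_subgraph(net, union)


@dataclass
class FflNullModelResult:
    z_random_nodes: np.ndarray  # model A: uniformly sampled node sets
    z_random_subnets: np.ndarray  # model B: sampled size-matched subnets
    mean_nodes: float
    sd_nodes: float
    mean_subnets: float
    sd_subnets: float

    def percentile_nodes(self, q: float) -> float:
        return float(np.nanpercentile(self.z_random_nodes, q))

    def percentile_subnets(self, q: float) -> float:
        return float(np.nanpercentile(self.z_random_subnets, q))


def _subsample_subnet(s: Subnet, size: int, rng: np.random.Generator) -> set[str]:
    """Uniform node subsample of a subnet retaining the root."""
    if size >= s.size:
        return set(s.members)
    others = sorted(s.members - {s.root})
    keep = rng.choice(len(others), size=size - 1, replace=False)
    return {s.root, *(others[i] for i in keep)}


def ffl_null_models(
    net: RegulatoryNetwork,
    subnets: Sequence[Subnet],
    n_nodes: int,
    subnet_size_profile: Sequence[int],
    n_samples: int = 100,
    n_random: int = 100,
    n_swap_multiplier: int = 100,
    seed: int = 0,
) -> FflNullModelResult:
    """Two null models for the FFL z-score of a cluster-induced subgraph.

    Model A scores induced subgraphs on ``n_samples`` uniformly sampled node
    sets of size ``n_nodes`` (the cluster's node count).  Model B draws the
    same number of subnets as the cluster contains, subsamples each (root
    retained) to the cluster's subnet-size profile, union-induces and scores.
    Both return the sample of FFL z-scores (NaN where a sampled graph has a
    degenerate null).
    """
    if n_nodes > net.n_nodes:
        raise ValueError("n_nodes exceeds network size")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)

    def ffl_z(sub: RegulatoryNetwork) -> float:
        sig = motif_zscores(
            sub, n_random=n_random, n_swap_multiplier=n_swap_multiplier,
            seed=int(rng.integers(2**31)),
        )
        return sig.z.get(FFL_ID, math.nan)

    z_a = np.empty(n_samples)
    for i in range(n_samples):
        picked = rng.choice(len(nodes), size=n_nodes, replace=False)
        assert picked.size == n_nodes
        z_a[i] = ffl_z(induced_subgraph(net, (nodes[p] for p in picked)))

    profile = list(subnet_size_profile)
    z_b = np.empty(n_samples)
    for i in range(n_samples):
        chosen = rng.choice(len(subnets), size=len(profile), replace=False)
        # pair the largest sampled subnets with the largest profile sizes so
        # the target sizes are attainable as often as possible
        picked_subnets = sorted((subnets[idx] for idx in chosen), key=lambda s: -s.size)
        union: set[str] = set()
        for s, size in zip(picked_subnets, sorted(profile, reverse=True)):
            union |= _subsample_subnet(s, size, rng)
        z_b[i] = ffl_z(induced_subgraph(net, union))

    return FflNullModelResult(
        z_random_nodes=z_a,
        z_random_subnets=z_b,
        mean_nodes=float(np.nanmean(z_a)),
        sd_nodes=float(np.nanstd(z_a)),
        mean_subnets=float(np.nanmean(z_b)),
        sd_subnets=float(np.nanstd(z_b)),
    )
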