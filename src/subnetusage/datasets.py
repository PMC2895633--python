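"""Small built-in example networks."""

from __future__ import annotations

from .network import InteractionRecord, RegulatoryNetwork, build_network

__all__ = ["example_network", "EXAMPLE_EDGES"]

#: Ten-node illustration of the subnet concept: root ``a`` reaches the whole
#: network (three hierarchical layers), root ``b`` the set {b,c,e,f,g}, root
#: ``d`` the set {d,g,h,i,k}.  Nodes a,b,c form a feed-forward loop and the
#: d subnet is a single input motif.
EXAMPLE_EDGES: tuple[tuple[str, str], ...] = (
    ("a", "b"), ("a", "c"), ("a", "d"),
    ("b", "c"), ("b", "e"), ("b", "f"), ("b", "g"),
    ("d", "g"), ("d", "h"), ("d", "i"), ("d", "k"),
)


def example_network() -> RegulatoryNetwork:
    """The 10-node, 11-edge example network with three subnets."""
    records = [InteractionRecord(u, v) for u, v in EXAMPLE_EDGES]
    return build_network(records, dimer_map={}, phantom_genes=())


def synthetic_subnet_catalog():
    """SYNTHETIC stand-in for a deposited 117-subnet catalog of the E. coli TRN.

    The real catalog is an external supplementary file; this generator
    fabricates a membership list with the same headline structure so the
    subnet-file dialect and its counting conventions can be exercised
    without the original data: 117 subnets in total, a dominant dimer-rooted
    subnet (``ihfAihfB``) of 1021 members, a mutually regulating root pair
    (``arcA``/``fnr``) sharing 650 downstream genes, a large regulon
    (``crp``) with 418 downstream genes, and a small single-input subnet
    (``agaR``) of 11 members.  All other entries are filler subnets of 5–30
    synthetic genes.  Returns a list of :class:`~subnetusage.subnets.Subnet`.
    """
    import numpy as np

    from .subnets import Subnet

    rng = np.random.default_rng(1021)
    pool = [f"gene{i:04d}" for i in range(2200)]

    shared = pool[:650]  # downstream genes common to arcA and fnr
    arca = Subnet("arcA", frozenset(["arcA", "fnr", *shared]))
    fnr = Subnet("fnr", frozenset(["fnr", "arcA", *shared]))
    ihf = Subnet("ihfAihfB", frozenset(["ihfAihfB", *pool[:1020]]))
    crp = Subnet("crp", frozenset(["crp", *pool[1020:1438]]))
    agar = Subnet("agaR", frozenset(["agaR", *pool[1438:1448]]))

    catalog = [ihf, arca, fnr, crp, agar]
    for i in range(112):
        size = int(rng.integers(5, 31))
        start = 1448 + (i * 6) % 700
        members = {f"root{i:03d}", *pool[start : start + size - 1]}
        catalog.append(Subnet(f"root{i:03d}", frozenset(members)))
    return catalog
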