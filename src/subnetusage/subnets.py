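"""Root-anchored subnet decomposition of a regulatory network.

The *subnet* of a root node is the subgraph induced by all nodes topologically
downstream of the root, including the root itself.  Every node with at least
one outgoing regulatory link anchors a subnet.  Because the TRN is almost
tree-like, most subnets are DAGs; the few small cycles are handled by
contracting strongly connected components, so that mutually regulating genes
share one hierarchical level and the "maximal distance to the root" stays
finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .network import RegulatoryNetwork

__all__ = [
    "Subnet",
    "NotARootError",
    "UndefinedOverlapError",
    "compute_subnet",
    "assign_levels",
    "enumerate_subnets",
    "relative_overlap",
    "shared_downstream",
    "write_subnet_file",
    "read_subnet_file",
]


class NotARootError(ValueError):
    """Raised when a subnet is requested for a node with no outgoing links."""


class UndefinedOverlapError(ValueError):
    """Relative overlap is undefined for empty sets."""


@dataclass(frozen=True)
class Subnet:
    """A root plus all genes reachable from it, with hierarchical levels.

    ``levels[g]`` is the maximal distance of ``g`` to the root, computed on
    the condensation of the subnet (genes in one strongly connected component
    share a level).  ``downstream_count`` excludes the root, ``size`` includes
    it — both conventions appear in the literature.
    """

    root: str
    members: frozenset[str]
    levels: Mapping[str, int] | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def downstream_count(self) -> int:
        return len(self.members) - 1

    @property
    def max_level(self) -> int:
        if not self.levels:
            return 0
        return max(self.levels.values())


def compute_subnet(net: RegulatoryNetwork, root: str, with_levels: bool = True) -> Subnet:
    """The subnet of ``root``: root plus every node reachable by directed paths.

    Self-loops are ignored (they live outside the analysis graph).  Raises
    :class:`NotARootError` if ``root`` has out-degree 0 or is absent.
    """
    g = net.graph
    if root not in g or g.out_degree(root) == 0:
        raise NotARootError(f"{root!r} is not a root (out-degree 0 or absent)")
    members = frozenset(nx.descendants(g, root)) | {root}
    levels = assign_levels(net, root, members) if with_levels else None
    return Subnet(root=root, members=members, levels=levels)


def assign_levels(
    net: RegulatoryNetwork, root: str, members: Iterable[str]
) -> dict[str, int]:
    """Hierarchical levels: longest path from the root on the SCC condensation.

    Strongly connected components inside the subnet are contracted, so a pair
    of mutually regulating genes (or the rare 3-cycle) shares one level; the
    level of a component is the longest condensation-path length from the
    root's component, and every member of the component gets that level.
    """
    members = set(members)
    sub = net.graph.subgraph(members)
    cond = nx.condensation(sub)  # a DAG; node attr 'members'
    comp_of = cond.graph["mapping"]
    root_comp = comp_of[root]
    dist = {root_comp: 0}
    for c in nx.topological_sort(cond):
        if c not in dist:
            continue  # unreachable from root's component (cannot happen here)
        for succ in cond.successors(c):
            if dist.get(succ, -1) < dist[c] + 1:
                dist[succ] = dist[c] + 1
    return {g: dist[comp_of[g]] for g in members}


def enumerate_subnets(
    net: RegulatoryNetwork, min_size: int = 5, with_levels: bool = True
) -> list[Subnet]:
    """One subnet per root (out-degree ≥ 1), kept if ``size ≥ min_size``.

    The default ``min_size`` of 5 restricts to subnets large enough for
    meaningful enrichment statistics.  Sorted by root name.
    """
    subnets = []
    for root in sorted(net.regulators):
        s = compute_subnet(net, root, with_levels=with_levels)
        if s.size >= min_size:
            subnets.append(s)
    return subnets


def relative_overlap(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / min(|A|, |B|) — overlap relative to the smaller set."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise UndefinedOverlapError("relative overlap undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def shared_downstream(a: Subnet, b: Subnet) -> int:
    """Number of downstream nodes (roots excluded) common to two subnets."""
    return len((a.members - {a.root, b.root}) & (b.members - {a.root, b.root}))


def write_subnet_file(subnets: Sequence[Subnet], path: str | Path) -> None:
    """One line per subnet, whitespace-separated gene names, root first."""
    with Path(path).open("w") as fh:
        for s in subnets:
            rest = sorted(s.members - {s.root})
            fh.write(" ".join([s.root, *rest]) + "\n")


def read_subnet_file(path: str | Path) -> list[tuple[str, frozenset[str]]]:
    """Read a subnet list: first token of each line is the root.

    A single-token line is a valid size-1 subnet; blank lines are skipped.
    Returns ``(root, members)`` pairs in file order, root included in members.
    """
    out: list[tuple[str, frozenset[str]]] = []
    with Path(path).open() as fh:
        for raw in fh:
            tokens = raw.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            out.append((tokens[0], frozenset(tokens)))
    return out
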