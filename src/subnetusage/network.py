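"""Construction of the gene-level transcriptional regulatory network (TRN).

The TRN is a directed graph whose nodes are genes and whose edges are
TF-mediated regulatory interactions (regulator → target).  Input tables come
as RegulonDB-style TSV exports.  Three normalisation steps are applied while
building the graph:

* **dimer merging** — genes whose products act only as a hetero-dimer
  (e.g. *ihfA*/*ihfB*, whose regulatory action is mediated by the IHF dimer)
  are collapsed to a single node;
* **phantom-gene removal** — entries that later curation rounds demoted from
  gene status are dropped;
* **self-loop routing** — autoregulatory edges are recorded as metadata but
  excluded from the analysis graph, so that reachability and the triad census
  operate on the loop-free graph.

Interaction signs (activation/repression) are parsed and stored on edges but
no downstream analysis consults them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "InteractionRecord",
    "RegulatoryNetwork",
    "ParseError",
    "ConfigurationError",
    "DEFAULT_DIMER_MAP",
    "read_interaction_table",
    "read_dimer_map",
    "read_gene_list",
    "build_network",
    "network_summary",
    "write_edge_list",
]

EFFECTS = ("activation", "repression", "dual", "unknown")

_EFFECT_TOKENS = {
    "+": "activation",
    "activation": "activation",
    "activator": "activation",
    "-": "repression",
    "repression": "repression",
    "repressor": "repression",
    "+-": "dual",
    "-+": "dual",
    "d": "dual",
    "dual": "dual",
    "?": "unknown",
    "unknown": "unknown",
}

#: Hetero-dimer TFs merged to a single node by default.  RegulonDB exports
#: list the constituent genes separately; their regulatory action is carried
#: by the dimer, so one node (and hence one subnet) represents each pair.
#: The list is a best effort and fully overridable.
DEFAULT_DIMER_MAP: dict[str, str] = {
    "ihfA": "ihfAihfB",
    "ihfB": "ihfAihfB",
    "flhC": "flhCflhD",
    "flhD": "flhCflhD",
    "gatR_1": "gatR2gatR1",
    "gatR_2": "gatR2gatR1",
    "rcsA": "rcsAB",
    "rcsB": "rcsAB",
}


class ParseError(ValueError):
    """A malformed line in an input table."""


class ConfigurationError(ValueError):
    """Inconsistent user-supplied configuration (e.g. conflicting dimer map)."""


@dataclass(frozen=True)
class InteractionRecord:
    """One regulator → target interaction, with an optional effect sign."""

    regulator: str
    target: str
    effect: str = "unknown"

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("regulator and target must be non-empty identifiers")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass
class RegulatoryNetwork:
    """Directed gene-level regulatory graph with self-loop bookkeeping.

    ``graph`` holds the loop-free analysis graph; autoregulatory genes are
    listed in ``self_loops``.  ``merged_from`` maps a merged dimer node to the
    original gene names it stands for.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    self_loops: set[str] = field(default_factory=set)
    merged_from: dict[str, list[str]] = field(default_factory=dict)
    #: lowercased gene → merged-node map used at build time (for name lookups)
    dimer_map: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        """Number of regulatory links in the analysis graph (self-loops excluded)."""
        return self.graph.number_of_edges()

    @property
    def regulators(self) -> set[str]:
        return {n for n, d in self.graph.out_degree() if d > 0}

    @property
    def targets(self) -> set[str]:
        return {n for n, d in self.graph.in_degree() if d > 0}

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            graph=self.graph.copy(),
            self_loops=set(self.self_loops),
            merged_from={k: list(v) for k, v in self.merged_from.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.self_loops == other.self_loops
        )


def _parse_effect(token: str) -> str:
    return _EFFECT_TOKENS.get(token.strip().lower(), "unknown")


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a TSV edge list: ``regulator TAB target [TAB effect]``.

    Lines starting with ``#`` and blank lines are skipped.  A non-comment
    line with fewer than two fields raises :class:`ParseError` naming the
    line number.  Order is preserved.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected ≥2 fields, got {len(fields)}")
            effect = _parse_effect(fields[2]) if len(fields) >= 3 else "unknown"
            records.append(InteractionRecord(fields[0], fields[1], effect))
    return records


def read_dimer_map(path: str | Path) -> dict[str, str]:
    """Read a gene TAB merged-node mapping file ('#' comments allowed)."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            mapping[fields[0]] = fields[1]
    return mapping


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line list ('#' comments allowed)."""
    names: list[str] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            names.append(line.split()[0])
    return names


class _NameRegistry:
    """Case-insensitive name canonicalisation: the first-seen spelling wins."""

    def __init__(self) -> None:
        self._canon: dict[str, str] = {}

    def resolve(self, name: str) -> str:
        key = name.lower()
        if key not in self._canon:
            self._canon[key] = name
        return self._canon[key]


def build_network(
    records: Iterable[InteractionRecord],
    dimer_map: Mapping[str, str] | None = None,
    phantom_genes: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Build the gene-level TRN from interaction records.

    Records touching a phantom gene are dropped; genes named in ``dimer_map``
    are replaced by the merged dimer node before edge construction; duplicate
    edges collapse (the first effect seen is kept); self-edges are routed to
    ``self_loops``.  Gene identifiers are matched case-insensitively, keeping
    the first-seen spelling.
    """
    dimer_map = dict(DEFAULT_DIMER_MAP) if dimer_map is None else dict(dimer_map)
    phantoms = {g.lower() for g in (phantom_genes or ())}

    # case-insensitive view of the dimer map, rejecting conflicts
    dimer_ci: dict[str, str] = {}
    for gene, merged in dimer_map.items():
        key = gene.lower()
        if key in dimer_ci and dimer_ci[key] != merged:
            raise ConfigurationError(
                f"gene {gene!r} mapped to both {dimer_ci[key]!r} and {merged!r}"
            )
        dimer_ci[key] = merged

    registry = _NameRegistry()
    merged_from: dict[str, set[str]] = {}

    def resolve(name: str) -> str | None:
        if name.lower() in phantoms:
            return None
        if name.lower() in dimer_ci:
            merged = dimer_ci[name.lower()]
            merged_from.setdefault(merged, set()).add(name)
            return registry.resolve(merged)
        return registry.resolve(name)

    net = RegulatoryNetwork()
    for rec in records:
        u = resolve(rec.regulator)
        v = resolve(rec.target)
        if u is None or v is None:
            continue
        if u == v:
            net.self_loops.add(u)
            net.graph.add_node(u)
        elif not net.graph.has_edge(u, v):
            net.graph.add_edge(u, v, effect=rec.effect)
    net.merged_from = {k: sorted(v) for k, v in merged_from.items()}
    net.dimer_map = dict(dimer_ci)
    return net


def _count_two_node_cycles(g: nx.DiGraph) -> int:
    return sum(1 for u, v in g.edges if u < v and g.has_edge(v, u))


def _count_three_node_cycles(g: nx.DiGraph) -> int:
    """Unordered triples {u,v,w} admitting a directed Hamiltonian 3-cycle.

    Each qualifying triple is counted once regardless of orientation; mutual
    (2-cycle) pairs alone never qualify.
    """
    triples: set[frozenset[str]] = set()
    for u, v in g.edges:
        for w in g.successors(v):
            if w != u and g.has_edge(w, u):
                triples.add(frozenset((u, v, w)))
    return len(triples)


def network_summary(net: RegulatoryNetwork) -> dict[str, int]:
    """Headline counts of the network: nodes, links, self-loops, regulators,
    targets, and small directed cycles."""
    g = net.graph
    return {
        "nodes": net.n_nodes,
        "links": net.n_links,
        "self_loops": len(net.self_loops),
        "regulators": len(net.regulators),
        "targets": len(net.targets),
        "two_node_cycles": _count_two_node_cycles(g),
        "three_node_cycles": _count_three_node_cycles(g),
    }


def write_edge_list(net: RegulatoryNetwork, path: str | Path, header: str | None = None) -> None:
    """Write the canonical TSV edge list (self-loops included as g TAB g)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in sorted(net.graph.edges):
            effect = net.graph.edges[u, v].get("effect", "unknown")
            fh.write(f"{u}\t{v}\t{effect}\n")
        for g in sorted(net.self_loops):
            fh.write(f"{g}\t{g}\tunknown\n")


def write_summary_json(net: RegulatoryNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_summary(net), indent=2) + "\n")
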