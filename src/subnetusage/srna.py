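"""Small-RNA target enrichment on subnets, motifs and usage clusters.

Small non-coding RNAs regulate mRNA stability and translation; here they are
represented only through their target gene set.  Targets are mapped onto the
network (case-insensitively, through the dimer map) and three questions are
asked: which subnets carry more targets than expected under a hypergeometric
null; which triad motifs contain targets more often than random target sets
of the same size; and how the enriched subnets distribute over the usage
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clustering import ClusterAssignment
from .motifs import connected_triads
from .network import RegulatoryNetwork
from .subnets import Subnet
from .usage_static import EnrichmentResult, adjust_enrichment, fisher_enrichment

__all__ = [
    "SrnaTargetSet",
    "map_targets",
    "subnet_target_enrichment",
    "motif_target_enrichment",
    "cluster_enrichment_fraction",
]


@dataclass
class SrnaTargetSet:
    mapped: frozenset[str]
    unmapped: list[str]
    n_input: int


def map_targets(raw_names: Iterable[str], net: RegulatoryNetwork) -> SrnaTargetSet:
    """Resolve raw target names onto network nodes.

    Names are matched case-insensitively and through the dimer map (a dimer
    constituent resolves to its merged node); duplicates collapse; names not
    found stay in ``unmapped``.
    """
    lower_nodes = {n.lower(): n for n in net.nodes}
    dimer_ci = dict(net.dimer_map)
    for merged, parts in net.merged_from.items():
        for p in parts:
            dimer_ci[p.lower()] = merged
    mapped: set[str] = set()
    unmapped: list[str] = []
    n_input = 0
    seen: set[str] = set()
    for name in raw_names:
        key = name.lower()
        if key in seen:
            continue
        seen.add(key)
        n_input += 1
        if key in dimer_ci and dimer_ci[key].lower() in lower_nodes:
            mapped.add(lower_nodes[dimer_ci[key].lower()])
        elif key in lower_nodes:
            mapped.add(lower_nodes[key])
        else:
            unmapped.append(name)
    return SrnaTargetSet(mapped=frozenset(mapped), unmapped=unmapped, n_input=n_input)


def subnet_target_enrichment(
    subnets: Sequence[Subnet],
    targets: SrnaTargetSet,
    background: Iterable[str],
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> tuple[set[str], list[EnrichmentResult]]:
    """One-sided Fisher test of target over-representation per subnet.

    Background defaults to all network nodes; p-values are corrected across
    all tested subnets.  Returns the enriched roots and the per-subnet
    results.  An empty target set yields p = 1 everywhere.
    """
    bg = set(background)
    results = [
        fisher_enrichment(targets.mapped, s.members, bg, root=s.root) for s in subnets
    ]
    adjust_enrichment(results, alpha=alpha, method=correction)
    if not targets.mapped:
        for r in results:
            r.significant = False
    enriched = {r.root for r in results if r.significant}
    return enriched, results


def motif_target_enrichment(
    net: RegulatoryNetwork,
    targets: SrnaTargetSet,
    n_samples: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Empirical p-value, per canonical triad id, that triads of that type
    contain at least one sRNA target more often than random target sets.

    The observed statistic is the number of triad instances with ≥ 1 target
    gene; the null redraws equally sized target sets uniformly from all
    network nodes ``n_samples`` times.  The +1-corrected empirical p is
    ``(1 + #{null ≥ observed}) / (n_samples + 1)`` — never exactly 0.
    """
    nodes = sorted(net.nodes)
    k = len(targets.mapped)
    if k > len(nodes):
        raise ValueError("target set larger than the node set")
    triads = list(connected_triads(net))
    ids = sorted({cid for _, cid in triads})

    def hit_counts(target_set: set[str]) -> dict[int, int]:
        counts = {cid: 0 for cid in ids}
        for trio, cid in triads:
            if any(g in target_set for g in trio):
                counts[cid] += 1
        return counts

    observed = hit_counts(set(targets.mapped))
    rng = np.random.default_rng(seed)
    exceed = {cid: 0 for cid in ids}
    for _ in range(n_samples):
        sample = {nodes[i] for i in rng.choice(len(nodes), size=k, replace=False)}
        null = hit_counts(sample)
        for cid in ids:
            if null[cid] >= observed[cid]:
                exceed[cid] += 1
    return {cid: (1 + exceed[cid]) / (n_samples + 1) for cid in ids}


def cluster_enrichment_fraction(
    assignment: ClusterAssignment,
    enriched_roots: Iterable[str],
    subnets: Sequence[Subnet],
) -> dict[str, float]:
    """Fraction of enriched subnets per usage cluster, plus the global fraction.

    Restricted to subnets present in the assignment; the global fraction is
    over all tested subnets (key ``"all"``).
    """
    enriched = set(enriched_roots)
    roots = [s.root for s in subnets]
    fractions: dict[str, float] = {}
    for label in assignment.mean_usage:
        members = [r for r in roots if assignment.labels.get(r) == label]
        fractions[label] = (
            sum(1 for r in members if r in enriched) / len(members) if members else 0.0
        )
    fractions["all"] = sum(1 for r in roots if r in enriched) / len(roots) if roots else 0.0
    return fractions
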