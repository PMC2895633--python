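"""Synthetic regulatory networks and expression data with planted structure.

Every stage of the analysis has a recovery test against known ground truth:
the generators emulate the salient features of a bacterial TRN — a sparse,
shallow hierarchy of regulators with heavy-tailed out-degrees, a handful of
feed-forward loops and rare mutual-regulation pairs — and of two-condition
and time-course microarray data with planted differential expression and
planted rank-1 collective responses.  They are test harnesses, not models of
transcription: probe effects, normalization artifacts and correlated noise
are deliberately absent.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import RegulatoryNetwork
from .subnets import Subnet, compute_subnet, enumerate_subnets

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "InfeasibleSpecError",
    "generate_trn",
    "generate_static_experiment",
    "generate_timecourse_experiment",
    "plant_srna_targets",
    "generate_usage_matrix",
]

log = logging.getLogger(__name__)


class InfeasibleSpecError(ValueError):
    """The requested structure cannot be planted (e.g. too many FFLs)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Desk-scale generative conditions for the synthetic study.

    Network: ``n_regulators`` TFs wired over at most ``hierarchy_depth``
    layers with Zipf(``out_degree_exponent``) out-degree weights,
    ``n_targets`` non-regulator genes, exactly ``ffl_count`` planted
    feed-forward triangles and ``two_cycle_count`` mutual TF pairs.

    Expression: log-scale values with i.i.d. Normal(0, ``noise_sd``) noise.
    Static comparisons shift genes of used subnets by ``effect_size``
    (penetrance ``penetrance``) with ``n_replicates`` arrays per condition;
    time courses give collective subnets a shared impulse profile of
    amplitude ``collective_amplitude`` over ``n_timepoints`` points.
    """

    n_regulators: int = 40
    n_targets: int = 400
    hierarchy_depth: int = 4
    out_degree_exponent: float = 2.0
    ffl_count: int = 20
    two_cycle_count: int = 2
    effect_size: float = 5.0
    penetrance: float = 1.0
    noise_sd: float = 1.0
    n_replicates: int = 8
    n_timepoints: int = 8
    collective_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regulators < 1:
            raise InfeasibleSpecError("need at least one regulator")
        if min(self.n_targets, self.hierarchy_depth) < 1:
            raise InfeasibleSpecError("n_targets and hierarchy_depth must be ≥ 1")
        if min(self.ffl_count, self.two_cycle_count) < 0:
            raise InfeasibleSpecError("counts must be ≥ 0")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0,1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    planted_used: dict[str, set[str]] = field(default_factory=dict)
    planted_collective: dict[str, set[str]] = field(default_factory=dict)
    planted_srna_enriched: set[str] = field(default_factory=set)


def _layer_sizes(n: int, depth: int) -> list[int]:
    """Partition n regulators into ≤ depth layers, geometrically growing."""
    depth = min(depth, n)
    weights = np.array([2.0**l for l in range(depth)])
    sizes = np.maximum(1, np.floor(n * weights / weights.sum()).astype(int))
    while sizes.sum() > n:
        sizes[np.argmax(sizes)] -= 1
    sizes[-1] += n - sizes.sum()
    return [int(s) for s in sizes]


def generate_trn(
    spec: SyntheticSpec,
    ffl_within_roots: Sequence[str] | None = None,
    min_subnet_size: int = 5,
) -> tuple[RegulatoryNetwork, list[Subnet]]:
    """Generate a layered, mostly acyclic TRN with planted motifs.

    Regulators are wired across layers (each non-top regulator has 1–2
    parents from shallower layers); targets attach to regulators with
    probability proportional to Zipf-distributed weights, echoing master
    regulators.  ``two_cycle_count`` mutual TF pairs are added first, then
    exactly ``ffl_count`` extra edges each closing a feed-forward triangle
    (restricted to the subnets of ``ffl_within_roots`` when given).  Returns
    the network and its subnets of at least ``min_subnet_size`` members.
    """
    rng = np.random.default_rng(spec.seed)
    regs = [f"tf{i:03d}" for i in range(spec.n_regulators)]
    targets = [f"g{i:04d}" for i in range(spec.n_targets)]

    sizes = _layer_sizes(spec.n_regulators, spec.hierarchy_depth)
    layer_of: dict[str, int] = {}
    pos = 0
    for l, s in enumerate(sizes):
        for r in regs[pos : pos + s]:
            layer_of[r] = l
        pos += s

    weights = np.minimum(rng.zipf(spec.out_degree_exponent, size=spec.n_regulators), 200).astype(float)

    net = RegulatoryNetwork()
    net.graph.add_nodes_from(regs)
    net.graph.add_nodes_from(targets)

    # TF → TF hierarchy edges
    for r in regs:
        l = layer_of[r]
        if l == 0:
            continue
        shallower = [p for p in regs if layer_of[p] < l]
        w = np.array([weights[regs.index(p)] for p in shallower])
        n_par = int(rng.integers(1, 3))
        chosen = rng.choice(len(shallower), size=min(n_par, len(shallower)), replace=False, p=w / w.sum())
        for c in chosen:
            net.graph.add_edge(shallower[c], r, effect="unknown")

    # targets attach to regulators ∝ weight
    p_reg = weights / weights.sum()
    for t in targets:
        n_par = 1 + rng.poisson(0.6)
        chosen = rng.choice(spec.n_regulators, size=min(n_par, spec.n_regulators), replace=False, p=p_reg)
        for c in chosen:
            net.graph.add_edge(regs[c], t, effect="unknown")

    # every regulator must be a root
    for r in regs:
        if net.graph.out_degree(r) == 0:
            t = targets[int(rng.integers(len(targets)))]
            net.graph.add_edge(r, t, effect="unknown")

    # mutual TF pairs (before FFL planting, so planted triads stay intact)
    tf_edges = [(u, v) for u, v in net.graph.edges if v in layer_of]
    rng.shuffle(tf_edges)
    planted_cycles = 0
    for u, v in tf_edges:
        if planted_cycles >= spec.two_cycle_count:
            break
        if not net.graph.has_edge(v, u):
            net.graph.add_edge(v, u, effect="unknown")
            planted_cycles += 1
    if planted_cycles < spec.two_cycle_count:
        raise InfeasibleSpecError("not enough TF-TF edges to plant 2-cycles")

    # FFL planting: close 2-paths u→v→w where the (u,w) pair is edge-free in
    # both directions and the triple is currently exactly a path, so adding
    # u→w makes the induced triad exactly a feed-forward loop
    g = net.graph
    allowed_u: set[str] | None = None
    allowed_nodes: set[str] | None = None
    if ffl_within_roots is not None:
        allowed_u = set(ffl_within_roots)
        allowed_nodes = set()
        for r in ffl_within_roots:
            allowed_nodes |= compute_subnet(net, r, with_levels=False).members
    candidates = []
    for u in (sorted(allowed_u) if allowed_u is not None else regs):
        if u not in g:
            continue
        for v in g.successors(u):
            for w in g.successors(v):
                if w == u or g.has_edge(u, w) or g.has_edge(w, u) or g.has_edge(v, u) or g.has_edge(w, v):
                    continue
                if allowed_nodes is not None and not {u, v, w} <= allowed_nodes:
                    continue
                candidates.append((u, v, w))
    rng.shuffle(candidates)
    planted_ffl = 0
    for u, v, w in candidates:
        if planted_ffl >= spec.ffl_count:
            break
        if g.has_edge(u, w) or g.has_edge(w, u):
            continue
        g.add_edge(u, w, effect="unknown")
        planted_ffl += 1
    if planted_ffl < spec.ffl_count:
        raise InfeasibleSpecError(
            f"only {planted_ffl} of {spec.ffl_count} feed-forward loops could be planted"
        )

    subnets = enumerate_subnets(net, min_size=min_subnet_size)
    return net, subnets


def _check_roots(net: RegulatoryNetwork, roots: Iterable[str]) -> list[Subnet]:
    subs = []
    for r in roots:
        subs.append(compute_subnet(net, r, with_levels=False))  # raises if not a root
    return subs


def generate_static_experiment(
    net: RegulatoryNetwork,
    used_roots: Iterable[str],
    spec: SyntheticSpec,
    seed: int | None = None,
    comparison_id: str = "synthetic",
) -> tuple[ExpressionMatrix, list[str], GroundTruth]:
    """Two-condition expression with planted differential expression.

    Baseline values are i.i.d. Normal(0, σ); in condition 2 every gene inside
    a used root's subnet is shifted by the effect size with probability equal
    to the penetrance.  Returns the matrix, the group labels (control/case
    per column) and the ground truth.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    used_subnets = _check_roots(net, used_roots)
    genes = sorted(net.nodes)
    R = spec.n_replicates
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), 2 * R))

    shifted: set[str] = set()
    for s in used_subnets:
        for gname in s.members:
            if rng.random() < spec.penetrance:
                shifted.add(gname)
    idx = {gname: i for i, gname in enumerate(genes)}
    for gname in shifted:
        values[idx[gname], R:] += spec.effect_size

    samples = [f"control_r{i}" for i in range(R)] + [f"case_r{i}" for i in range(R)]
    labels = ["control"] * R + ["case"] * R
    df = pd.DataFrame(values, index=genes, columns=samples)
    expr = ExpressionMatrix(values=df, sample_annotation=dict(zip(samples, labels)))
    truth = GroundTruth(planted_used={comparison_id: {s.root for s in used_subnets}})
    return expr, labels, truth


def _impulse_profile(T: int) -> np.ndarray:
    """Rise–decay impulse over T points, peak normalized to 1."""
    t = np.linspace(0.0, 1.0, T)
    tau = 0.25
    prof = (t / tau) * np.exp(1.0 - t / tau)
    return prof / prof.max()


def generate_timecourse_experiment(
    net: RegulatoryNetwork,
    collective_roots: Iterable[str],
    spec: SyntheticSpec,
    seed: int | None = None,
    experiment_id: str = "synthetic_tc",
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Time course with planted rank-1 collective subnets.

    Genes of collective subnets follow gene-specific scale × a shared impulse
    profile plus Normal(0, σ) noise; all other genes are pure noise.
    """
    if spec.n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subs = _check_roots(net, collective_roots)
    genes = sorted(net.nodes)
    T = spec.n_timepoints
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), T))

    profile = _impulse_profile(T) * spec.collective_amplitude
    collective_genes: set[str] = set()
    for s in subs:
        collective_genes |= s.members
    idx = {gname: i for i, gname in enumerate(genes)}
    for gname in sorted(collective_genes):
        scale = rng.uniform(0.5, 1.5) * (1 if rng.random() < 0.7 else -1)
        values[idx[gname]] += scale * profile

    samples = [f"t{k}" for k in range(T)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    expr = ExpressionMatrix(
        values=df, sample_annotation={s: k for k, s in enumerate(samples)}
    )
    truth = GroundTruth(planted_collective={experiment_id: {s.root for s in subs}})
    return expr, truth


def plant_srna_targets(
    net: RegulatoryNetwork,
    enriched_roots: Iterable[str],
    base_rate: float = 0.02,
    enrich_factor: float = 10.0,
    seed: int = 0,
) -> tuple[list[str], GroundTruth]:
    """Random sRNA target list with over-represented targets in chosen subnets.

    Each gene becomes a target with probability ``base_rate``, multiplied by
    ``enrich_factor`` inside the enriched subnets (capped at 1, with a
    warning).
    """
    rng = np.random.default_rng(seed)
    subs = _check_roots(net, enriched_roots)
    inside: set[str] = set()
    for s in subs:
        inside |= s.members
    p_in = base_rate * enrich_factor
    if p_in > 1.0:
        log.warning("base_rate × enrich_factor > 1; capped at 1")
        p_in = 1.0
    names: list[str] = []
    for gname in sorted(net.nodes):
        p = p_in if gname in inside else base_rate
        if rng.random() < p:
            names.append(gname)
    truth = GroundTruth(planted_srna_enriched={s.root for s in subs})
    return names, truth


def generate_usage_matrix(
    n_strong: int = 12,
    n_medium: int = 12,
    n_null: int = 12,
    n_conditions: int = 80,
    strong_rate: float = 0.25,
    medium_rate: float = 0.05,
    strong_response: float = 0.9,
    medium_response: float = 0.85,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Binary usage matrix with three planted usage-rate groups.

    Null subnets are never used.  The strong and medium groups each respond
    as a block: a condition is group-active with probability
    ``rate / response`` (at least 3 active conditions are forced) and, when
    it is, each subnet of the group is used with probability ``response`` —
    reproducing the blocks of coordinately used subnets seen in real usage
    matrices while keeping the marginal usage at ``strong_rate`` and
    ``medium_rate``.  Returns the matrix and the planted group of each row.
    """
    rng = np.random.default_rng(seed)
    roots = (
        [f"strong{i:02d}" for i in range(n_strong)]
        + [f"medium{i:02d}" for i in range(n_medium)]
        + [f"null{i:02d}" for i in range(n_null)]
    )
    truth = {r: r.rstrip("0123456789") for r in roots}
    M = np.zeros((len(roots), n_conditions), dtype=int)

    def block_rows(n_rows: int, rate: float, response: float) -> np.ndarray:
        active = rng.random(n_conditions) < rate / response
        while active.sum() < 3:
            active[int(rng.integers(n_conditions))] = True
        block = rng.random((n_rows, n_conditions)) < response
        return (block & active[None, :]).astype(int)

    M[:n_strong] = block_rows(n_strong, strong_rate, strong_response)
    M[n_strong : n_strong + n_medium] = block_rows(n_medium, medium_rate, medium_response)
    usage = pd.DataFrame(M, index=roots, columns=[f"cond{j:02d}" for j in range(n_conditions)])
    return usage, truth
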