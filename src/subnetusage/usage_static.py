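"""Static (two-condition) subnet usage.

For each two-condition comparison, differentially expressed genes are called
with a SAM-style permutation procedure on a standardized Wilcoxon rank-sum
statistic; each subnet is then tested for over-representation of the called
genes with a one-sided Fisher's exact test, and the per-comparison p-values
are corrected for multiple testing across subnets.  A subnet is *used* in a
comparison when its corrected enrichment p-value clears the significance
level; the binary subnets × comparisons matrix is the static usage matrix.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .subnets import Subnet

__all__ = [
    "DifferentialCallSet",
    "EnrichmentResult",
    "wilcoxon_statistic",
    "sam_call",
    "fisher_enrichment",
    "build_static_usage",
]

log = logging.getLogger(__name__)


@dataclass
class DifferentialCallSet:
    comparison_id: str
    statistic: dict[str, float]
    delta: float
    fdr_estimate: float
    called: frozenset[str]


@dataclass
class EnrichmentResult:
    root: str
    table: tuple[int, int, int, int]  # (in∧called, in∧not, out∧called, out∧not)
    p_value: float
    p_adjusted: float = math.nan
    significant: bool = False


def _rank_sum_stats(n_a: int, n_b: int, ties: np.ndarray) -> tuple[float, float]:
    """Null mean and sd of the group-a rank sum, with tie correction."""
    n = n_a + n_b
    mean = n_a * (n + 1) / 2.0
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    return mean, math.sqrt(max(var, 0.0))


def wilcoxon_statistic(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Standardized Wilcoxon rank-sum statistic of group a vs group b.

    Midranks for ties; the rank sum of group a is centred and scaled by its
    permutation-null moments (with tie correction).  Positive values mean
    group a ranks higher.  Fully tied data yields 0 (no division blow-up).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = ranks[: a.size].sum()
    _, ties = np.unique(pooled, return_counts=True)
    mean, sd = _rank_sum_stats(a.size, b.size, ties)
    if sd == 0.0:
        return 0.0
    return (w - mean) / sd


def _group_indices(labels: Sequence[object]) -> tuple[np.ndarray, np.ndarray, list[object]]:
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    lab = np.asarray(labels, dtype=object)
    return np.flatnonzero(lab == uniq[0]), np.flatnonzero(lab == uniq[1]), uniq


def _statistics_for_assignment(values: np.ndarray, idx_a: np.ndarray) -> np.ndarray:
    """Row-wise standardized rank-sum statistics for one label assignment."""
    n_genes, n = values.shape
    n_a = idx_a.size
    mask = np.zeros(n, dtype=bool)
    mask[idx_a] = True
    out = np.empty(n_genes)
    for i in range(n_genes):
        ranks = stats.rankdata(values[i])
        w = ranks[mask].sum()
        _, ties = np.unique(values[i], return_counts=True)
        mean, sd = _rank_sum_stats(n_a, n - n_a, ties)
        out[i] = 0.0 if sd == 0.0 else (w - mean) / sd
    return out


def sam_call(
    expr: ExpressionMatrix,
    labels: Sequence[object],
    q: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    comparison_id: str = "",
) -> DifferentialCallSet:
    """SAM permutation procedure on the rank-sum statistic.

    Observed per-gene statistics are sorted and compared with their expected
    order statistics (the mean of sorted statistics over ``n_perm`` label
    permutations; all distinct assignments are enumerated exactly when fewer
    exist).  At a threshold ``delta`` a gene is called when its observed
    order statistic deviates from the expected one by more than ``delta`` in
    the consistent direction.  FDR(delta) is the median, over permutations,
    of the number of permuted statistics beyond the data-derived cuts,
    divided by the number called; the reported ``delta`` is the smallest one
    with FDR ≤ ``q``.  No fudge factor is applied to the rank statistic.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0,1)")
    idx_a, idx_b, _ = _group_indices(labels)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("need at least 2 samples per group")
    values = expr.values.to_numpy(dtype=float)
    genes = np.asarray(expr.genes)
    n = values.shape[1]
    n_a = idx_a.size

    n_distinct = math.comb(n, n_a)
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct label permutations")
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        assignments = [np.array(c) for c in itertools.combinations(range(n), n_a)]
    else:
        assignments = [
            np.sort(rng.choice(n, size=n_a, replace=False)) for _ in range(n_perm)
        ]

    d_obs = _statistics_for_assignment(values, idx_a)
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]

    perm_stats = np.empty((len(assignments), len(genes)))
    for b, idx in enumerate(assignments):
        perm_stats[b] = np.sort(_statistics_for_assignment(values, idx))
    d_expected = perm_stats.mean(axis=0)

    diff = d_sorted - d_expected

    def call_at(delta: float) -> tuple[np.ndarray, float]:
        # data-derived cuts: the least extreme observed value whose deviation
        # from its expected order statistic reaches delta; everything beyond
        # the cut is called (the classic first-crossing rule)
        up = (diff >= delta) & (diff > 0)
        down = (diff <= -delta) & (diff < 0)
        cut_up = d_sorted[up].min() if up.any() else math.inf
        cut_low = d_sorted[down].max() if down.any() else -math.inf
        called_mask = (d_sorted >= cut_up) | (d_sorted <= cut_low)
        n_called = int(called_mask.sum())
        if n_called == 0:
            return called_mask, 0.0
        beyond = ((perm_stats >= cut_up) | (perm_stats <= cut_low)).sum(axis=1)
        fdr = float(np.median(beyond)) / n_called
        return called_mask, fdr

    candidates = np.unique(np.abs(diff))
    candidates = candidates[candidates > 0]
    chosen_delta = math.inf
    chosen_mask = np.zeros(len(genes), dtype=bool)
    chosen_fdr = math.nan
    for delta in candidates:
        mask, fdr = call_at(float(delta))
        if fdr <= q:
            chosen_delta, chosen_mask, chosen_fdr = float(delta), mask, fdr
            break

    called_genes = frozenset(genes[order][chosen_mask])
    return DifferentialCallSet(
        comparison_id=comparison_id,
        statistic=dict(zip(genes, d_obs)),
        delta=chosen_delta,
        fdr_estimate=chosen_fdr,
        called=called_genes,
    )


def fisher_enrichment(
    called: Iterable[str], subnet_members: Iterable[str], background: Iterable[str],
    root: str = "",
) -> EnrichmentResult:
    """One-sided over-representation test of called genes inside a subnet.

    The p-value is the hypergeometric tail probability of observing at least
    the seen number of called genes among the subnet's genes, drawing from
    the background.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    sub = set(subnet_members) & bg
    hits = set(called) & bg
    k = len(sub & hits)
    table = (k, len(sub) - k, len(hits) - k, len(bg) - len(sub) - len(hits) + k)
    p = float(stats.hypergeom.sf(k - 1, len(bg), len(hits), len(sub)))
    return EnrichmentResult(root=root, table=table, p_value=min(p, 1.0))


def adjust_enrichment(
    results: Sequence[EnrichmentResult], alpha: float = 0.05, method: str = "fdr_bh"
) -> None:
    """Benjamini–Hochberg (or Bonferroni/Holm) correction across subnets, in place."""
    if not results:
        return
    pvals = [r.p_value for r in results]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
    for r, pa, rej in zip(results, p_adj, reject):
        r.p_adjusted = float(pa)
        r.significant = bool(rej)


@dataclass
class StaticUsageResult:
    usage: pd.DataFrame  # subnets (rows) × comparisons (cols), binary
    skipped: list[str]
    enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    calls: dict[str, DifferentialCallSet] = field(default_factory=dict)


def build_static_usage(
    comparisons: Sequence[tuple[ExpressionMatrix, Sequence[object]]],
    subnets: Sequence[Subnet],
    trn_genes: Iterable[str],
    q: float = 0.05,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    correction: str = "fdr_bh",
    comparison_ids: Sequence[str] | None = None,
    background: str = "intersection",
) -> StaticUsageResult:
    """Build the binary static usage matrix over all comparisons.

    Per comparison: run :func:`sam_call`; a comparison with no called genes
    is skipped (no column).  Otherwise each subnet is tested for enrichment
    against the background — TRN genes measured in the comparison
    (``background="intersection"``, default) or all TRN genes
    (``background="trn"``) — corrected across subnets, and the usage entry
    is 1 iff the adjusted p-value is ≤ ``alpha``.
    """
    trn_genes = set(trn_genes)
    roots = [s.root for s in subnets]
    if comparison_ids is None:
        comparison_ids = [f"comparison_{i}" for i in range(len(comparisons))]
    columns: dict[str, pd.Series] = {}
    skipped: list[str] = []
    result = StaticUsageResult(usage=pd.DataFrame(index=roots, dtype=int), skipped=skipped)
    for cid, (expr, labels) in zip(comparison_ids, comparisons):
        calls = sam_call(expr, labels, q=q, n_perm=n_perm, seed=seed, comparison_id=cid)
        result.calls[cid] = calls
        if not calls.called:
            skipped.append(cid)
            continue
        measured = set(expr.genes)
        bg = (trn_genes & measured) if background == "intersection" else trn_genes
        enrich: list[EnrichmentResult] = []
        for s in subnets:
            present = s.members & bg
            if len(present) < 1:
                log.warning("subnet %s has no genes in comparison %s", s.root, cid)
                enrich.append(EnrichmentResult(root=s.root, table=(0, 0, 0, 0), p_value=1.0))
                continue
            enrich.append(fisher_enrichment(calls.called, present, bg, root=s.root))
        adjust_enrichment(enrich, alpha=alpha, method=correction)
        result.enrichment[cid] = enrich
        columns[cid] = pd.Series(
            [int(r.significant) for r in enrich], index=roots, dtype=int
        )
    result.usage = pd.DataFrame(columns, index=roots, dtype=int) if columns else pd.DataFrame(index=roots, dtype=int)
    return result
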