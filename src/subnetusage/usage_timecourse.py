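"""Time-course subnet usage via SVD entropy.

A subnet responds *collectively* during a time course when its genes' profiles
are dominated by one shared mode.  This is quantified by the Shannon entropy
of the normalized squared singular values of the time-points × genes
submatrix: a rank-1 (perfectly collective) response has entropy 0, maximally
incoherent expression has entropy 1.  Each subnet's entropy is standardized
against pseudo-subnets — random gene sets of the same size — giving a
z-score; strongly negative z means the subnet is far more collective than
random gene sets.  The z cutoff is either set directly or calibrated so that
a target fraction of subnets is never collective (matching the static data's
share of never-used subnets).

The meta-analysis variant for large heterogeneous compendia drops the
principal singular value before normalizing, removing chip-wide global
variation.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .subnets import Subnet

__all__ = [
    "CollectivityResult",
    "DegenerateNullError",
    "svd_entropy",
    "collectivity_z",
    "calibrate_cutoff",
    "build_timecourse_usage",
    "TimecourseUsageResult",
]

log = logging.getLogger(__name__)


class DegenerateNullError(ValueError):
    """The pseudo-subnet entropy distribution has zero spread."""


@dataclass
class CollectivityResult:
    root: str
    n_genes_measured: int
    entropy: float
    null_mean: float
    null_sd: float
    z: float
    n_pseudo: int
    collective: bool = False


def svd_entropy(M: np.ndarray, drop_principal: bool = False) -> float:
    """Shannon entropy of the normalized squared singular values of ``M``.

    With singular values ``s_k``, let ``p_k = s_k² / Σ_j s_j²``; the entropy
    is ``−(1/ln N) Σ p_k ln p_k`` with ``N`` the number of retained values
    (``min(rows, cols)``, one less when ``drop_principal``) and 0·ln 0 := 0.
    Invariant under row/column permutation and global rescaling; 0 iff the
    matrix is rank 1, 1 iff all retained singular values are equal.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    s = np.linalg.svd(M, compute_uv=False)
    if drop_principal:
        s = s[1:]
    if s.size < 2:
        raise ValueError("fewer than 2 singular values retained")
    total = float((s**2).sum())
    if total == 0.0:
        raise ValueError("entropy undefined for an (effectively) all-zero matrix")
    p = s**2 / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(s.size))


def collectivity_z(
    expr: ExpressionMatrix,
    subnet_genes: Iterable[str],
    n_pseudo: int = 1000,
    seed: int = 0,
    drop_principal: bool = False,
    root: str = "",
    min_genes: int = 3,
) -> CollectivityResult:
    """Entropy z-score of a subnet against size-matched pseudo-subnets.

    ``n_pseudo`` random gene sets of the same size are drawn without
    replacement from all genes measured in the experiment; the z-score is
    the deviation of the subnet's entropy from the sampled mean in units of
    the sampled standard deviation.  Deterministic given ``seed``.
    """
    genes = [g for g in subnet_genes if g in expr.values.index]
    if len(genes) < min_genes:
        raise ValueError(
            f"subnet {root or '?'}: only {len(genes)} genes measured (need ≥ {min_genes})"
        )
    values = expr.values  # genes × time points
    sub = values.loc[genes].to_numpy(dtype=float).T  # time × genes
    entropy = svd_entropy(sub, drop_principal=drop_principal)

    all_genes = np.asarray(values.index)
    k = len(genes)
    rng = np.random.default_rng(seed)
    arr = values.to_numpy(dtype=float)
    null = np.empty(n_pseudo)
    for i in range(n_pseudo):
        idx = rng.choice(all_genes.size, size=k, replace=False)
        assert idx.size == k
        null[i] = svd_entropy(arr[idx].T, drop_principal=drop_principal)
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    if sd == 0.0:
        raise DegenerateNullError(f"subnet {root or '?'}: pseudo-subnet entropies degenerate")
    z = (entropy - mean) / sd
    return CollectivityResult(
        root=root,
        n_genes_measured=k,
        entropy=entropy,
        null_mean=mean,
        null_sd=sd,
        z=z,
        n_pseudo=n_pseudo,
    )


def calibrate_cutoff(z_matrix: pd.DataFrame | np.ndarray, target_null_fraction: float) -> float:
    """Choose the z cutoff that makes the never-collective fraction match a target.

    A subnet (row) is *null* at cutoff ``c`` when none of its experiment
    z-scores is ≤ ``c``.  The returned cutoff minimizes the absolute
    difference between the realized null fraction and
    ``target_null_fraction``, scanning all observed z values (plus a −∞
    sentinel); ties break toward the more conservative (lower) cutoff.
    NaN entries (subnets not measurable in an experiment) are ignored;
    all-NaN rows are excluded.
    """
    if not 0.0 <= target_null_fraction <= 1.0:
        raise ValueError("target_null_fraction must be in [0,1]")
    Z = np.asarray(z_matrix, dtype=float)
    if Z.size == 0:
        raise ValueError("empty z matrix")
    row_ok = ~np.all(np.isnan(Z), axis=1)
    Z = Z[row_ok]
    if Z.size == 0:
        raise ValueError("no measurable subnets in z matrix")
    row_min = np.nanmin(Z, axis=1)
    candidates = np.concatenate([[-math.inf], np.unique(Z[np.isfinite(Z)])])
    best_c, best_err = -math.inf, math.inf
    for c in candidates:  # ascending; keep the lowest cutoff on ties
        frac_null = float(np.mean(row_min > c))
        err = abs(frac_null - target_null_fraction)
        if err < best_err - 1e-15:
            best_err, best_c = err, float(c)
    return best_c


@dataclass
class TimecourseUsageResult:
    usage: pd.DataFrame  # subnets × experiments, binary
    z_matrix: pd.DataFrame  # subnets × experiments, NaN where not measurable
    cutoff: float
    results: dict[tuple[str, str], CollectivityResult]


def build_timecourse_usage(
    experiments: Sequence[ExpressionMatrix],
    subnets: Sequence[Subnet],
    n_pseudo: int = 1000,
    seed: int = 0,
    cutoff: float | None = None,
    target_null_fraction: float | None = 0.25,
    drop_principal: bool = False,
    experiment_ids: Sequence[str] | None = None,
    min_genes: int = 3,
) -> TimecourseUsageResult:
    """Binary time-course usage matrix: entry 1 iff z(subnet, experiment) ≤ cutoff.

    Subnets with fewer than ``min_genes`` measured genes in an experiment get
    a NaN z (and usage 0, with a log note).  When ``cutoff`` is None the
    cutoff is calibrated from the full z matrix to ``target_null_fraction``.
    """
    if experiment_ids is None:
        experiment_ids = [f"experiment_{i}" for i in range(len(experiments))]
    roots = [s.root for s in subnets]
    Z = pd.DataFrame(np.nan, index=roots, columns=list(experiment_ids))
    results: dict[tuple[str, str], CollectivityResult] = {}
    for eid, expr in zip(experiment_ids, experiments):
        for j, s in enumerate(subnets):
            eid_hash = zlib.crc32(str(eid).encode()) % (2**31)
            sub_seed = np.random.default_rng([seed, eid_hash, j]).integers(2**31)
            try:
                res = collectivity_z(
                    expr, s.members, n_pseudo=n_pseudo, seed=int(sub_seed),
                    drop_principal=drop_principal, root=s.root, min_genes=min_genes,
                )
            except (ValueError, DegenerateNullError) as exc:
                log.info("skipping %s in %s: %s", s.root, eid, exc)
                continue
            Z.loc[s.root, eid] = res.z
            results[(s.root, eid)] = res
    if cutoff is None:
        if target_null_fraction is None:
            raise ValueError("either cutoff or target_null_fraction is required")
        cutoff = calibrate_cutoff(Z, target_null_fraction) if Z.size else -math.inf
    usage = (Z <= cutoff).astype(int)
    for (root, eid), res in results.items():
        res.collective = bool(usage.loc[root, eid])
    return TimecourseUsageResult(usage=usage, z_matrix=Z, cutoff=float(cutoff), results=results)
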