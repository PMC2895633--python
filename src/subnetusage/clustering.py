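"""Hierarchical clustering of subnets by their binary usage rows.

Subnets are clustered on the Manhattan distance between usage rows with the
Ward agglomerative criterion and the tree cut into a fixed number of groups
(three by default), labelled by descending mean usage: *strong*, *medium*,
*null*.  Two Ward variants are offered: the classic Lance–Williams update
applied directly to the Manhattan distances ("ward.D", the default) and Ward
on squared distances ("ward.D2").  Cluster compositions from different data
sets are compared with the relative-overlap measure (shared subnets divided
by the smaller cluster).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .subnets import relative_overlap

__all__ = [
    "ClusterAssignment",
    "hier_cluster",
    "label_clusters",
    "cluster_overlap",
    "dendrogram_newick",
]

log = logging.getLogger(__name__)

LABELS_K3 = ("strong", "medium", "null")


@dataclass
class ClusterAssignment:
    labels: dict[str, str]  # subnet root → cluster label
    mean_usage: dict[str, float]  # label → mean usage
    k: int

    def roots_with_label(self, label: str) -> set[str]:
        return {r for r, l in self.labels.items() if l == label}


def _linkage(usage: pd.DataFrame, variant: str) -> np.ndarray:
    dist = pdist(usage.to_numpy(dtype=float), metric="cityblock")
    if variant == "ward.D":
        # scipy's ward recurrence squares its input internally, so feeding
        # sqrt(d) applies Lance–Williams Ward directly to the distances d
        return linkage(np.sqrt(dist), method="ward")
    if variant == "ward.D2":
        return linkage(dist, method="ward")
    raise ValueError(f"unknown ward variant {variant!r}")


def hier_cluster(
    usage: pd.DataFrame, k: int = 3, variant: str = "ward.D"
) -> list[set[str]]:
    """Partition usage rows into ``k`` groups by Ward clustering.

    Rows are sorted lexicographically by root before computing distances so
    the result is deterministic; empty (all-skipped) columns are dropped
    first.  Raises when ``k`` exceeds the number of rows.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k > usage.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows ({usage.shape[0]})")
    usage = usage.sort_index()
    usage = usage.loc[:, usage.notna().any(axis=0)] if usage.shape[1] else usage
    if usage.shape[1] == 0:
        raise ValueError("usage matrix has no columns")
    if k == usage.shape[0]:
        return [{r} for r in usage.index]
    Z = _linkage(usage, variant)
    flat = fcluster(Z, t=k, criterion="maxclust")
    groups: dict[int, set[str]] = {}
    for root, g in zip(usage.index, flat):
        groups.setdefault(int(g), set()).add(root)
    return [groups[g] for g in sorted(groups)]


def label_clusters(partition: list[set[str]], usage: pd.DataFrame) -> ClusterAssignment:
    """Label clusters by descending mean usage.

    For k = 3 the labels are strong/medium/null; otherwise strong,
    medium_1…medium_{k−2}, null.  Equal means are broken by cluster size
    (the larger cluster ranks closer to *strong*; logged).
    """
    k = len(partition)
    means = [float(usage.loc[sorted(group)].to_numpy(dtype=float).mean()) for group in partition]
    order = sorted(range(k), key=lambda i: (-means[i], -len(partition[i])))
    for i, j in zip(order, order[1:]):
        if means[i] == means[j]:
            log.info("mean-usage tie between clusters; larger cluster ranked higher")
    if k == 3:
        names = list(LABELS_K3)
    elif k == 1:
        names = ["strong"]
    elif k == 2:
        names = ["strong", "null"]
    else:
        names = ["strong", *[f"medium_{i}" for i in range(1, k - 1)], "null"]
    labels: dict[str, str] = {}
    mean_usage: dict[str, float] = {}
    for rank, idx in enumerate(order):
        mean_usage[names[rank]] = means[idx]
        for root in partition[idx]:
            labels[root] = names[rank]
    return ClusterAssignment(labels=labels, mean_usage=mean_usage, k=k)


def cluster_overlap(a: ClusterAssignment, b: ClusterAssignment) -> pd.DataFrame:
    """Relative overlap between cluster root-sets of two assignments.

    Restricted to the roots both assignments share; entry (la, lb) is
    |A∩B| / min(|A|,|B|) over the restricted root sets (NaN when a class is
    empty on the shared universe).
    """
    shared = set(a.labels) & set(b.labels)
    if not shared:
        raise ValueError("assignments share no subnet roots")
    labels_a = sorted(a.mean_usage, key=lambda l: -a.mean_usage[l])
    labels_b = sorted(b.mean_usage, key=lambda l: -b.mean_usage[l])
    table = pd.DataFrame(np.nan, index=labels_a, columns=labels_b)
    for la in labels_a:
        ra = a.roots_with_label(la) & shared
        for lb in labels_b:
            rb = b.roots_with_label(lb) & shared
            if ra and rb:
                table.loc[la, lb] = relative_overlap(ra, rb)
    return table


def dendrogram_newick(usage: pd.DataFrame, variant: str = "ward.D") -> str:
    """Newick export of the full usage dendrogram (leaf names = roots)."""
    usage = usage.sort_index()
    Z = _linkage(usage, variant)
    tree = to_tree(Z)
    names = list(usage.index)

    def render(node) -> str:
        if node.is_leaf():
            return f"{names[node.id]}:{node.dist:.6g}"
        return f"({render(node.left)},{render(node.right)}):{node.dist:.6g}"

    return f"({render(tree.left)},{render(tree.right)});"
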