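"""Coexpression-module detection: soft-thresholded adjacency, topological
overlap, Ward hierarchical clustering with a tree-variant dynamic cut, and
per-cluster GO enrichment.

The adjacency raises the (negative-clipped) normalized coexpression matrix
to a soft-threshold power beta=12, which suppresses weak relationships while
keeping the network weighted. Topological overlap then rewards pairs that
share neighbors:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_u a_iu and TOM_ii = 1. Clustering runs Ward
linkage on the dissimilarity 1 - TOM; the dendrogram is cut at a fixed
fraction of its merge-height range and only branches with at least
``min_cluster_size`` members become clusters (label 0 = unassigned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .proportionality import CoexpressionMatrix
from .stats import bh_adjust, fisher_exact

__all__ = [
    "ClusterAssignment", "adjacency_power", "tom_similarity",
    "cluster_tom", "cluster_go_enrichment", "cluster_class_fractions",
]


def adjacency_power(coex: CoexpressionMatrix, beta: int = 12,
                    clip_negative: bool = True) -> pd.DataFrame:
    """Soft-thresholded adjacency a = max(rho, 0)^beta, zero diagonal.

    Missing rho counts as no adjacency; negative rho is clipped to zero
    (unsigned network) before powering.
    """
    R = coex.rho.to_numpy().copy()
    R[np.isnan(R)] = 0.0
    if clip_negative:
        np.clip(R, 0.0, None, out=R)
    A = R ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=coex.orf_ids, columns=coex.orf_ids)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of a weighted adjacency matrix."""
    A = adjacency.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(A)).max() > 0:
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ClusterAssignment:
    labels: pd.Series                    # orf -> cluster label, 0 unassigned
    min_cluster_size: int
    cut_height_fraction: float

    def cluster_ids(self):
        return sorted(set(self.labels) - {0})

    def members(self, cluster: int):
        return self.labels.index[self.labels == cluster]


def cluster_tom(tom: pd.DataFrame, min_cluster_size: int = 20,
                cut_height_fraction: float = 0.5) -> ClusterAssignment:
    """Ward clustering of 1 - TOM with a static branch cut.

    The dendrogram is cut at ``cut_height_fraction`` of the range between
    the smallest and largest merge height (the basic "tree" flavor of
    dynamic branch cutting); branches of at least ``min_cluster_size``
    members become clusters, relabeled 1..K by descending size.
    """
    if tom.shape[0] < 2:
        raise ValueError("need at least two ORFs to cluster")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="ward")
    heights = Z[:, 2]
    if heights[-1] <= heights[0] or np.allclose(heights, heights[0]):
        raw = np.ones(tom.shape[0], dtype=int)     # degenerate: one cluster
    else:
        h = heights[0] + cut_height_fraction * (heights[-1] - heights[0])
        raw = fcluster(Z, t=h, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_cluster_size]
    order = keep.sort_values(ascending=False).index
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = pd.Series([remap.get(r, 0) for r in raw], index=tom.index,
                       name="cluster")
    return ClusterAssignment(labels, min_cluster_size, cut_height_fraction)


def cluster_class_fractions(assignment: ClusterAssignment,
                            classes: pd.Series) -> pd.Series:
    """Noncanonical fraction per cluster."""
    cls = classes.reindex(assignment.labels.index)
    out = {}
    for c in assignment.cluster_ids():
        members = assignment.members(c)
        out[c] = float((cls.loc[members] == "noncanonical").mean())
    return pd.Series(out, name="noncanonical_fraction")


def cluster_go_enrichment(assignment: ClusterAssignment, classes: pd.Series,
                          genesets: dict, min_canonical: int = 5,
                          fdr: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher GO enrichment of each cluster's canonical members.

    The background is every canonical ORF in the coexpression matrix;
    clusters with fewer than ``min_canonical`` canonical members are
    skipped. BH correction runs across all (cluster, term) tests.
    """
    cls = classes.reindex(assignment.labels.index)
    background = set(assignment.labels.index[cls == "canonical"])
    n_bg = len(background)
    fractions = cluster_class_fractions(assignment, cls)
    rows = []
    for c in assignment.cluster_ids():
        members = set(assignment.members(c))
        canon = members & background
        if len(canon) < min_canonical:
            continue
        for term, genes in genesets.items():
            g_bg = set(genes) & background
            k = len(canon & g_bg)
            table = [[k, len(canon) - k],
                     [len(g_bg) - k, n_bg - len(canon) - len(g_bg) + k]]
            res = fisher_exact(table, sided="greater")
            rows.append({
                "cluster": c, "term": term,
                "n_in_cluster": k, "cluster_canonical": len(canon),
                "n_background": len(g_bg), "background_size": n_bg,
                "odds_ratio": res.value, "p": res.p,
                "noncanonical_fraction": fractions.get(c, float("nan")),
            })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"])
        df["significant"] = df["fdr"] < fdr
    return df
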