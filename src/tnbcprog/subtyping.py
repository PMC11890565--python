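"""Intrinsic subtype assignment by nearest-centroid correlation.

Samples are assigned the subtype whose reference centroid profile has the
highest Spearman correlation with the sample's (subgroup-centered)
expression over the centroid genes.  Claudin-low status is called on top of
the intrinsic labels by a dual criterion: centroid positivity plus
membership in a majority-positive cluster of a complete-linkage Euclidean
dendrogram over an intrinsic gene list.

Centroids and centering vectors are always inputs (published centroid files
can be dropped in); nothing is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

__all__ = ["CentroidSet", "subgroup_center", "assign_subtype", "call_claudin_low"]

UNASSIGNABLE = "unassignable"


@dataclass
class CentroidSet:
    """Reference profiles (genes x subtypes) plus a subgroup centering vector."""

    centroids: pd.DataFrame
    centering: pd.Series | None = None

    def __post_init__(self):
        if self.centroids.shape[1] < 2:
            raise ValueError("need at least two subtype centroids")
        if self.centering is not None:
            missing = self.centroids.index.difference(self.centering.index)
            if len(missing):
                raise ValueError(
                    f"centering vector lacks centroid genes: {list(missing[:5])}"
                )

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)


def subgroup_center(expr: pd.DataFrame, centering: pd.Series) -> pd.DataFrame:
    """Subtract per-gene subgroup reference values (genes x samples input).

    The centering vector holds, for each gene, the reference value of the
    clinical subgroup the samples belong to, so that samples from subgroups
    with different marker baselines become comparable before centroid
    correlation.
    """
    missing = expr.index.difference(centering.index)
    if len(missing):
        raise ValueError(f"genes missing from centering vector: {list(missing[:10])}")
    return expr.sub(centering.loc[expr.index], axis=0)


def assign_subtype(expr: pd.DataFrame, centroids: CentroidSet | pd.DataFrame):
    """Nearest-centroid subtype call per sample (genes x samples input).

    Returns ``(labels, correlations, flags)``: the argmax subtype per
    sample, the full sample x subtype Spearman correlation matrix, and a
    flag series ('' / 'tie' / 'constant_profile').  Exact ties go to the
    first subtype in declared column order; constant sample profiles are
    labeled 'unassignable'.
    """
    cset = centroids if isinstance(centroids, CentroidSet) else CentroidSet(centroids)
    shared = expr.index.intersection(cset.centroids.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared with the centroids")
    X = expr.loc[shared].to_numpy(dtype=float)  # genes x samples
    C = cset.centroids.loc[shared].to_numpy(dtype=float)  # genes x subtypes
    # Spearman = Pearson on ranks
    Xr = np.apply_along_axis(rankdata, 0, X)
    Cr = np.apply_along_axis(rankdata, 0, C)
    Xc = Xr - Xr.mean(axis=0)
    Cc = Cr - Cr.mean(axis=0)
    xn = np.sqrt((Xc**2).sum(axis=0))
    cn = np.sqrt((Cc**2).sum(axis=0))
    constant = xn == 0
    xn = np.where(constant, 1.0, xn)
    corr = (Xc.T @ Cc) / np.outer(xn, cn)  # samples x subtypes
    labels = []
    flags = []
    names = cset.subtypes
    for i, sample in enumerate(expr.columns):
        if constant[i]:
            labels.append(UNASSIGNABLE)
            flags.append("constant_profile")
            continue
        row = corr[i]
        best = np.max(row)
        winners = np.flatnonzero(row >= best - 1e-12)
        labels.append(names[winners[0]])
        flags.append("tie" if winners.size > 1 else "")
    corr_df = pd.DataFrame(corr, index=expr.columns, columns=names)
    return (
        pd.Series(labels, index=expr.columns, name="subtype"),
        corr_df,
        pd.Series(flags, index=expr.columns, name="flag"),
    )


def call_claudin_low(
    expr: pd.DataFrame,
    centroids: CentroidSet | pd.DataFrame,
    *,
    claudin_label: str = "claudin_low",
    intrinsic_genes=None,
    n_clusters: int | None = None,
):
    """Dual-criteria claudin-low call (genes x samples input).

    A sample is claudin-low iff (a) its correlation to the claudin-low
    centroid strictly exceeds its correlation to every other centroid, and
    (b) it falls in a cluster — complete linkage, Euclidean distance, over
    the intrinsic gene list, cut at ``n_clusters`` (default: number of
    subtypes + 1) — in which more than half the members satisfy (a).
    Singleton clusters satisfy the majority rule trivially and are flagged.

    Returns ``(is_claudin_low, flags)`` boolean/str series per sample.
    """
    cset = centroids if isinstance(centroids, CentroidSet) else CentroidSet(centroids)
    if claudin_label not in cset.subtypes:
        raise ValueError(f"centroids have no {claudin_label!r} column")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    _, corr, _ = assign_subtype(expr, cset)
    others = [s for s in cset.subtypes if s != claudin_label]
    positive = corr[claudin_label] > corr[others].max(axis=1)

    genes = pd.Index(intrinsic_genes) if intrinsic_genes is not None else expr.index
    genes = genes.intersection(expr.index)
    if len(genes) == 0:
        raise ValueError("intrinsic gene list does not overlap the expression matrix")
    k = n_clusters if n_clusters is not None else len(cset.subtypes) + 1
    k = min(k, expr.shape[1])
    Z = linkage(expr.loc[genes].T.to_numpy(dtype=float), method="complete", metric="euclidean")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    clusters = pd.Series(assignment, index=expr.columns)

    is_cl = pd.Series(False, index=expr.columns, name=claudin_label)
    flags = pd.Series("", index=expr.columns, name="flag")
    for cid, members in clusters.groupby(clusters):
        ids = members.index
        frac = positive.loc[ids].mean()
        if frac > 0.5:
            is_cl.loc[ids] = positive.loc[ids]
            if len(ids) == 1:
                flags.loc[ids] = "singleton_cluster"
    return is_cl, flags
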