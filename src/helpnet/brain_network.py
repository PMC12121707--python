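"""Correlation-threshold functional networks from region activity.

Inter-region Pearson correlations of c-Fos density across subjects are
thresholded at the top decile of pairwise values; pairs above the cutoff
become (unweighted) edges and regions with degree >= 1 are considered
connected to the network. Clusters come from average-linkage hierarchical
agglomeration on the distance 1 - r.

The cutoff is the value at rank ceil((1 - fraction) * Npairs) of the
ascending-sorted upper triangle, and edges require r strictly above it, so
with ties at the cutoff fewer edges than fraction * Npairs may survive.
By default the decile is taken over SIGNED correlations (the strongest
positive couplings); ``mode='absolute'`` ranks |r| instead.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from statsmodels.stats.multitest import multipletests

from helpnet.behavior import pearson_with_p
from helpnet.data_model import ActivityMatrix, ValidationError

__all__ = [
    "CorrelationNetwork",
    "correlation_matrix",
    "threshold_top_decile",
    "cluster_network",
    "region_behavior_screen",
    "to_graph",
]


@dataclass
class CorrelationNetwork:
    r_matrix: np.ndarray  # (p, p) symmetric, unit diagonal
    region_ids: list[str]
    cutoff: float
    adjacency: np.ndarray  # (p, p) bool, zero diagonal
    fraction: float
    mode: str = "signed"
    clusters: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        adj = self.adjacency
        if not np.array_equal(adj, adj.T) or adj.diagonal().any():
            raise ValidationError("adjacency must be symmetric with a zero diagonal")

    @property
    def degree(self) -> pd.Series:
        return pd.Series(
            self.adjacency.sum(axis=1).astype(int), index=self.region_ids
        )

    @property
    def connected_regions(self) -> list[str]:
        """Regions with at least one supra-threshold edge."""
        deg = self.adjacency.sum(axis=1)
        return [r for r, d in zip(self.region_ids, deg) if d >= 1]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def correlation_matrix(
    m: ActivityMatrix, condition: Optional[str] = None
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Pearson correlations of region densities across subjects.

    A constant region column has undefined correlations; its row/column is
    set to NaN with a warning rather than silently zeroed.
    """
    values = m.values if condition is None else m.values[m.condition_mask(condition)]
    if values.shape[0] < 3:
        raise ValidationError("need at least 3 subjects to correlate regions")
    if np.isnan(values).any():
        raise ValidationError("missing values present; interpolate first")
    sd = values.std(axis=0)
    constant = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(values, rowvar=False)
    if constant.any():
        names = [rid for rid, c in zip(m.region_ids, constant) if c]
        warnings.warn(
            f"constant region column(s) {names[:5]}: correlations set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    return r, list(m.region_ids)


def threshold_top_decile(
    r_matrix: np.ndarray,
    region_ids: Sequence[str],
    fraction: float = 0.10,
    mode: str = "signed",
) -> CorrelationNetwork:
    """Keep the top ``fraction`` of pairwise correlations as edges."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    r = np.asarray(r_matrix, dtype=float)
    p = r.shape[0]
    if r.shape != (p, p) or p < 3:
        raise ValidationError("r_matrix must be square with p >= 3")
    iu = np.triu_indices(p, k=1)
    vals = r[iu] if mode == "signed" else np.abs(r[iu])
    if np.isnan(vals).any():
        raise ValidationError("NaN correlations present; drop those regions first")
    n_pairs = vals.size
    rank = math.ceil((1 - fraction) * n_pairs)  # 1-based in ascending order
    cutoff = float(np.sort(vals)[rank - 1])
    adjacency = np.zeros((p, p), dtype=bool)
    above = vals > cutoff
    adjacency[iu[0][above], iu[1][above]] = True
    adjacency |= adjacency.T
    return CorrelationNetwork(
        r_matrix=r,
        region_ids=[str(x) for x in region_ids],
        cutoff=cutoff,
        adjacency=adjacency,
        fraction=fraction,
        mode=mode,
    )


def cluster_network(
    net: CorrelationNetwork, k: int, method: str = "average"
) -> dict[str, int]:
    """Partition regions into k clusters by hierarchical agglomeration.

    Distance is 1 - r on the full correlation matrix (not the thresholded
    adjacency), so weakly connected regions still cluster with their most
    correlated neighbors. Deterministic given the inputs; cluster ids are
    1..k in scipy's leaf order.
    """
    p = len(net.region_ids)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}, got {k}")
    dist = 1.0 - net.r_matrix
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # symmetrize fp noise for squareform
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method=method)
    labels = scipy.cluster.hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    clusters = {rid: int(c) for rid, c in zip(net.region_ids, labels)}
    net.clusters = clusters
    return clusters


def region_behavior_screen(
    m: ActivityMatrix,
    behavior: Mapping[str, float],
    regions: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region Pearson correlation of density with a behavioral measure.

    Returns one row per region with r, the two-sided p, a significance
    flag at ``alpha`` (uncorrected, matching how such screens are usually
    reported), and a Benjamini-Hochberg adjusted column for users who want
    multiplicity control.
    """
    missing = [s for s in m.subject_ids if s not in behavior]
    if missing:
        raise ValidationError(f"behavior values missing for subject(s) {missing[:5]}")
    y = np.array([behavior[s] for s in m.subject_ids], dtype=float)
    region_ids = list(m.region_ids) if regions is None else list(regions)
    col = {rid: j for j, rid in enumerate(m.region_ids)}
    unknown = [rid for rid in region_ids if rid not in col]
    if unknown:
        raise ValidationError(f"unknown region(s) {unknown[:5]}")
    rows = []
    for rid in region_ids:
        r, p = pearson_with_p(m.values[:, col[rid]], y)
        rows.append({"region_id": rid, "r": r, "p": p})
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha
    df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def to_graph(net: CorrelationNetwork) -> nx.Graph:
    """Export as a networkx graph (edges carry the underlying r)."""
    g = nx.Graph()
    for i, rid in enumerate(net.region_ids):
        attrs = {}
        if net.clusters is not None:
            attrs["cluster"] = net.clusters[rid]
        g.add_node(rid, **attrs)
    p = len(net.region_ids)
    for i in range(p):
        for j in range(i + 1, p):
            if net.adjacency[i, j]:
                g.add_edge(
                    net.region_ids[i], net.region_ids[j], r=float(net.r_matrix[i, j])
                )
    return g
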