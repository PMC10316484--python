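"""Graph-theoretic summary of the directed connectivity matrix.

Four per-site metrics — strength (total in+out weight), closeness,
betweenness and transitivity — plus PCA compression of the metric table
into the oceanographic-connectivity (OC) predictor block.

By default shortest-path metrics treat the connection weight as a *cost*
(edge length = raw weight), replicating the convention of the igraph-based
analysis this pipeline mirrors, under which higher closeness/betweenness
indicate a higher degree of isolation.  ``weight_semantics="cost_inverse"``
(edge length = 1/weight) is the semantically conventional alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import DirectedMatrix, ValidationError

__all__ = ["NetworkMetrics", "PcaBlock", "network_metrics", "pca_block"]


@dataclass
class NetworkMetrics:
    table: pd.DataFrame  # index: site_id; columns: strength, closeness, betweenness, transitivity
    weight_semantics: str


def network_metrics(c: DirectedMatrix, weight_semantics: str = "cost_raw") -> NetworkMetrics:
    """Strength, closeness, betweenness and transitivity per site.

    Zero-weight entries are absent edges (not zero-cost edges); the
    diagonal is ignored.  Transitivity is the local clustering coefficient
    on the binarized undirected graph.
    """
    if weight_semantics not in ("cost_raw", "cost_inverse"):
        raise ValueError("weight_semantics must be 'cost_raw' or 'cost_inverse'")
    W = c.values.copy()
    np.fill_diagonal(W, 0.0)
    n = len(c.site_ids)
    if not (W > 0).any():
        warnings.warn("all-zero connectivity matrix: path metrics undefined")

    strength = W.sum(axis=1) + W.sum(axis=0)

    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                length = W[i, j] if weight_semantics == "cost_raw" else 1.0 / W[i, j]
                G.add_edge(i, j, length=length)

    # outward closeness: computed on the reversed graph so distances run
    # from the focal site to the others (igraph mode="out" analogue)
    closeness = nx.closeness_centrality(G.reverse(), distance="length")
    betweenness = nx.betweenness_centrality(G, weight="length", normalized=False)

    U = nx.Graph()
    U.add_nodes_from(range(n))
    U.add_edges_from((i, j) for i in range(n) for j in range(i + 1, n) if W[i, j] > 0 or W[j, i] > 0)
    transitivity = nx.clustering(U)

    table = pd.DataFrame(
        {
            "strength": strength,
            "closeness": [closeness[i] for i in range(n)],
            "betweenness": [betweenness[i] for i in range(n)],
            "transitivity": [transitivity[i] for i in range(n)],
        },
        index=pd.Index(c.site_ids, name="site_id"),
    )
    return NetworkMetrics(table=table, weight_semantics=weight_semantics)


@dataclass
class PcaBlock:
    scores: pd.DataFrame  # site x retained axes
    variance_share: np.ndarray  # all axes, non-increasing
    n_axes: int


def pca_block(
    metrics: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    n_axes: int | None = 3,
    cum_var: float | None = None,
) -> PcaBlock:
    """PCA of the (centred, scaled) metric table; retains a fixed axis
    count (default 3) or the smallest count reaching ``cum_var``.

    Constant columns are dropped with a warning before scaling.
    """
    if len(metrics) < 2:
        raise ValidationError("PCA needs at least 2 sites")
    X = metrics.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing values")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant columns: {list(metrics.columns[~keep])}")
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValidationError("no non-constant columns for PCA")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S**2
    share = var / var.sum()
    scores_all = U * S
    if cum_var is not None:
        k = int(np.searchsorted(np.cumsum(share), cum_var) + 1)
    else:
        k = min(n_axes or 3, scores_all.shape[1])
    k = min(k, scores_all.shape[1])
    scores = pd.DataFrame(
        scores_all[:, :k], index=metrics.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaBlock(scores=scores, variance_share=share, n_axes=k)
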