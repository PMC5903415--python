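"""Global, nodal and community-level summary metrics of correlation networks.

Deliberately elementary measures — degree, weighted degree, nodal strength,
edge density, Euclidean connection distance, within/between-community edge
density — since bootstrap-thresholded networks have variable density and
higher-order graph statistics are strongly density-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CorrelationMatrix, ThresholdedNetwork

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "nodal_and_global_metrics",
    "community_density",
]


@dataclass
class NodalMetrics:
    degree: np.ndarray             # retained edges per node
    weighted_degree: np.ndarray    # sum of retained edge weights
    strength: np.ndarray           # mean unthresholded correlation per row
    connection_distance: np.ndarray  # mean retained edge length, NaN if isolated


@dataclass
class GlobalMetrics:
    mean_correlation: float        # off-diagonal mean of unthresholded r
    edge_density_pct: float        # retained edges as % of possible
    mean_connection_distance: float  # mean length over retained edges, NaN if none


def nodal_and_global_metrics(
    net: ThresholdedNetwork,
    corr: CorrelationMatrix,
    centroids: np.ndarray,
) -> tuple[NodalMetrics, GlobalMetrics]:
    """Compute nodal and global metrics for one thresholded network.

    Nodal strength is taken from the unthresholded correlation row (diagonal
    excluded); connection distances use 3-D Euclidean distance between
    anatomical centroids. Isolated nodes get NaN nodal distance and enter the
    global distance only through their (absent) edges.
    """
    n = net.n_regions
    if corr.n_regions != n or centroids.shape != (n, 3):
        raise ValueError("dimension mismatch between network, correlation, centroids")
    mask = net.mask
    degree = mask.sum(axis=1)
    weighted_degree = net.weights.sum(axis=1)
    strength = (corr.weights.sum(axis=1) - 1.0) / (n - 1)

    dist = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nodal_dist = np.where(degree > 0, (dist * mask).sum(axis=1) / degree, np.nan)

    iu = np.triu_indices(n, 1)
    possible = n * (n - 1) // 2
    n_edges = int(mask[iu].sum())
    mean_dist = float(dist[iu][mask[iu]].mean()) if n_edges else float("nan")
    nodal = NodalMetrics(
        degree=degree,
        weighted_degree=weighted_degree,
        strength=strength,
        connection_distance=nodal_dist,
    )
    glob = GlobalMetrics(
        mean_correlation=corr.mean_offdiagonal(),
        edge_density_pct=100.0 * n_edges / possible,
        mean_connection_distance=mean_dist,
    )
    return nodal, glob


def community_density(net: ThresholdedNetwork, labels) -> np.ndarray:
    """Within/between-community edge density matrix D.

    ``D[a, a]`` is retained within-community edges over m(m-1)/2 possible;
    ``D[a, b]`` is retained between-community edges over m_a * m_b possible.
    Communities of size 1 get NaN within-density (no possible edges).
    Returned in the order of sorted unique labels.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != net.n_regions:
        raise ValueError("every region must carry a community label")
    communities = np.unique(labels)
    k = len(communities)
    D = np.full((k, k), np.nan)
    mask = net.mask
    members = [np.flatnonzero(labels == c) for c in communities]
    for a in range(k):
        ma = members[a]
        possible_within = len(ma) * (len(ma) - 1) / 2
        if possible_within > 0:
            D[a, a] = mask[np.ix_(ma, ma)].sum() / 2 / possible_within
        for b in range(a + 1, k):
            mb = members[b]
            D[a, b] = D[b, a] = mask[np.ix_(ma, mb)].sum() / (len(ma) * len(mb))
    return D
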