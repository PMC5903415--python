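"""Multiresolution Louvain communities, versatility, consensus, and NMI.

The community structure of a weighted correlation network is found with the
Louvain modularity algorithm at resolution gamma (Newman-Girvan modularity
with gamma scaling the null term; negative weights are excluded from the
modularity graph). Because Louvain is stochastic, the resolution is chosen by
minimizing nodal *versatility* — the co-assignment uncertainty of node pairs
across repeated runs — and the final partition is a Lancichinetti-Fortunato
consensus: re-cluster the thresholded co-assignment matrix until all runs
agree. Partitions are compared with normalized mutual information (NMI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "CommunityPartition",
    "VersatilityCurve",
    "louvain_partition",
    "versatility_curve",
    "consensus_partition",
    "nmi",
]


@dataclass
class CommunityPartition:
    labels: np.ndarray            # region -> module, contiguous from 1
    gamma: float
    n_runs: int = 1
    is_consensus: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1:
            raise ValueError("labels must be 1-based")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class VersatilityCurve:
    gammas: np.ndarray
    mean_versatility: np.ndarray   # per-gamma mean nodal versatility, in [0, 1]
    modal_module_count: np.ndarray
    recommended_gammas: np.ndarray  # local minima of the smoothed curve


def _positive_graph(weights: np.ndarray) -> nx.Graph:
    w = np.asarray(weights, dtype=float)
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    g = nx.from_numpy_array(w)
    zero = [(u, v) for u, v, d in g.edges(data=True) if d.get("weight", 0) <= 0]
    g.remove_edges_from(zero)
    return g


def _canonical_labels(communities, n: int) -> np.ndarray:
    """1-based labels ordered by each module's smallest node index."""
    labels = np.zeros(n, dtype=int)
    ordered = sorted(communities, key=min)
    for lab, nodes in enumerate(ordered, start=1):
        labels[list(nodes)] = lab
    return labels


def louvain_partition(weights: np.ndarray, gamma: float = 1.0,
                      seed: int = 0) -> CommunityPartition:
    """One (stochastic) Louvain run at resolution gamma on positive weights."""
    g = _positive_graph(weights)
    n = g.number_of_nodes()
    if g.number_of_edges() == 0:
        warnings.warn("all-zero network: returning a single module", stacklevel=2)
        return CommunityPartition(labels=np.ones(n, dtype=int), gamma=gamma)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=int(seed)
    )
    return CommunityPartition(labels=_canonical_labels(comms, n), gamma=gamma)


def _coassignment(label_runs: np.ndarray) -> np.ndarray:
    """Proportion of runs assigning each node pair to the same module."""
    n_runs, n = label_runs.shape
    P = np.zeros((n, n))
    for run in label_runs:
        P += run[:, None] == run[None, :]
    return P / n_runs


def _run_batch(weights, gamma, n_runs, rng) -> np.ndarray:
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    return np.vstack(
        [louvain_partition(weights, gamma, seed=s).labels for s in seeds]
    )


def versatility_curve(weights, gamma_grid, n_runs: int = 100,
                      seed: int = 0) -> VersatilityCurve:
    """Mean nodal versatility across a resolution grid.

    For each gamma, Louvain runs ``n_runs`` times; with p_ij the co-assignment
    proportion of nodes i and j, nodal versatility is
    ``V_i = mean_{j != i} 4 p_ij (1 - p_ij)`` — 0 when module affiliation is
    perfectly consistent across runs, maximal (1) for a 50:50 split.
    Recommended resolutions are local minima of the 3-point-smoothed curve.
    """
    if n_runs < 2:
        raise ValueError("versatility needs at least 2 runs")
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = np.asarray(weights).shape[0]
    mean_v = np.empty(len(gamma_grid))
    modal_k = np.empty(len(gamma_grid), dtype=int)
    for gi, gamma in enumerate(gamma_grid):
        runs = _run_batch(weights, gamma, n_runs, rng)
        P = _coassignment(runs)
        V = 4.0 * P * (1.0 - P)
        np.fill_diagonal(V, 0.0)
        mean_v[gi] = V.sum() / (n * (n - 1))
        counts = [len(np.unique(r)) for r in runs]
        modal_k[gi] = int(np.bincount(counts).argmax())
    if np.allclose(mean_v, 0.0) and np.all(modal_k == 1):
        warnings.warn("single-module solutions at every gamma", stacklevel=2)
    if len(gamma_grid) >= 3:
        smoothed = np.convolve(np.pad(mean_v, 1, mode="edge"),
                               np.ones(3) / 3, "valid")
        is_min = np.r_[False, (smoothed[1:-1] <= smoothed[:-2])
                       & (smoothed[1:-1] <= smoothed[2:]), False]
        # a single-module solution is trivially consistent (V = 0); only
        # resolutions with nontrivial modal partitions are recommended
        is_min &= modal_k >= 2
    else:
        is_min = np.zeros(len(gamma_grid), dtype=bool)
    return VersatilityCurve(
        gammas=gamma_grid,
        mean_versatility=mean_v,
        modal_module_count=modal_k,
        recommended_gammas=gamma_grid[is_min],
    )


def consensus_partition(weights, gamma: float = 1.0, n_runs: int = 1000,
                        tau: float = 0.5, seed: int = 0,
                        max_iter: int = 20) -> CommunityPartition:
    """Consensus clustering over repeated Louvain runs.

    Builds the co-assignment matrix over ``n_runs`` partitions, zeroes entries
    below ``tau``, re-clusters the consensus matrix, and repeats until every
    run returns the same partition (up to relabeling). Deterministic given
    ``seed``.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    runs = _run_batch(weights, gamma, n_runs, rng)
    if n_runs == 1:
        return CommunityPartition(labels=runs[0], gamma=gamma, n_runs=1,
                                  is_consensus=True)
    for _ in range(max_iter):
        if all(np.array_equal(_relabel(r), _relabel(runs[0])) for r in runs):
            return CommunityPartition(labels=_relabel(runs[0]), gamma=gamma,
                                      n_runs=n_runs, is_consensus=True)
        P = _coassignment(runs)
        P[P < tau] = 0.0
        np.fill_diagonal(P, 0.0)
        runs = _run_batch(P, 1.0, n_runs, rng)
    warnings.warn("consensus did not converge; returning last partition",
                  stacklevel=2)
    return CommunityPartition(labels=_relabel(runs[0]), gamma=gamma,
                              n_runs=n_runs, is_consensus=True)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Canonical 1-based relabeling by order of first appearance."""
    _, inverse = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(labels)
    nxt = 1
    for i, lab in enumerate(labels):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[i] = first[lab]
    return out


def nmi(p1, p2) -> float:
    """Normalized mutual information, 2 I(X;Y) / (H(X) + H(Y)), in [0, 1].

    Relabel-invariant. When both partitions are single-module (both entropies
    zero) the partitions are identical and NMI is defined as 1 by convention.
    """
    a = p1.labels if isinstance(p1, CommunityPartition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, CommunityPartition) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same region set")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1.0)
    pxy = contingency / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx == 0.0 and hy == 0.0:
        return 1.0
    nz = pxy > 0
    mi = np.sum(pxy[nz] * (np.log(pxy[nz]) - np.log(np.outer(px, py)[nz])))
    return float(np.clip(2.0 * mi / (hx + hy), 0.0, 1.0))
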