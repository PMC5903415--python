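"""Pearson correlation networks with bootstrap-FDR probabilistic thresholding.

A correlation network over a participant subset is the sample Pearson r of
every region pair, computed on raw morphometry values (no covariate
adjustment). Thresholding is probabilistic: the subset is resampled with
replacement B times, each resample re-estimating the whole matrix, and an edge
is tested for a sign-consistent (nonzero) correlation across resamples. The
two-tailed sign-crossing p-value

    p = 2 * min(#{r*_b <= 0}, #{r*_b >= 0}) / B        (capped at 1)

is 0 exactly when the edge is consistently positive or consistently negative
across all B resamples. Edge-wise p-values are adjusted with Benjamini-
Hochberg and edges with adjusted p below ``alpha`` retain their observed
(full-subset) correlation; all other edges are set to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dataset import CorticalDataset

__all__ = [
    "BootstrapConfig",
    "CorrelationMatrix",
    "ThresholdedNetwork",
    "correlation_matrix",
    "decompose_correlation",
    "bootstrap_edge_pvalues",
    "fdr_adjust",
    "threshold_network",
    "build_thresholded_network",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    n_boot: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("need at least 2 bootstrap resamples")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class CorrelationMatrix:
    """Symmetric region x region Pearson r with provenance."""

    weights: np.ndarray
    n_participants: int
    participant_subset: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(self.n_regions, 1)
        return float(self.weights[iu].mean())


@dataclass
class ThresholdedNetwork:
    """Bootstrap-thresholded network: retained weights, mask, edge statistics."""

    weights: np.ndarray          # observed r where retained, 0 elsewhere
    mask: np.ndarray             # boolean retention mask (diagonal False)
    p: np.ndarray                # per-edge bootstrap sign-crossing p
    p_adj: np.ndarray            # BH-adjusted p
    n_positive: int
    n_negative: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.mask[np.triu_indices(self.n_regions, 1)].sum())

    def edge_list(self):
        """Edge table (i, j, r, p, p_adj, retained) over the upper triangle."""
        import pandas as pd

        iu = np.triu_indices(self.n_regions, 1)
        return pd.DataFrame(
            {
                "region_i": iu[0],
                "region_j": iu[1],
                "r": np.where(self.mask[iu], self.weights[iu], np.nan),
                "p": self.p[iu],
                "p_adj": self.p_adj[iu],
                "retained": self.mask[iu],
            }
        )


def _subset_values(dataset, participant_subset) -> np.ndarray:
    if isinstance(dataset, CorticalDataset):
        values = dataset.values.to_numpy(float)
    else:
        values = np.asarray(dataset, float)
    if participant_subset is not None:
        values = values[np.asarray(participant_subset)]
    return values


def _check_variance(values: np.ndarray) -> None:
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if len(dead):
        raise ValueError(f"zero-variance region(s) in subset: {dead.tolist()}")


def correlation_matrix(dataset, participant_subset=None) -> CorrelationMatrix:
    """Sample Pearson correlation of every region pair over a participant subset."""
    values = _subset_values(dataset, participant_subset)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 participants to correlate")
    _check_variance(values)
    r = np.corrcoef(values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    subset = None if participant_subset is None else np.asarray(participant_subset)
    return CorrelationMatrix(weights=r, n_participants=values.shape[0],
                             participant_subset=subset)


def decompose_correlation(dataset, participant_subset=None):
    """Split the correlation into its covariance and SD-product components.

    Returns ``(mean_cov, mean_sd_product, ratio)``: the mean over off-diagonal
    region pairs of cov(i, j), the mean of sd(i)*sd(j), and their ratio (the
    numerator and denominator of Pearson's r, averaged separately; the ratio
    is in general not equal to the mean correlation).
    """
    values = _subset_values(dataset, participant_subset)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    _check_variance(values)
    cov = np.cov(values, rowvar=False)
    sd = np.sqrt(np.diag(cov))
    iu = np.triu_indices(cov.shape[0], 1)
    mean_cov = float(cov[iu].mean())
    mean_sdprod = float(np.outer(sd, sd)[iu].mean())
    return mean_cov, mean_sdprod, mean_cov / mean_sdprod


def bootstrap_edge_pvalues(dataset, participant_subset, config: BootstrapConfig):
    """Two-tailed sign-crossing p per edge over whole-matrix bootstrap resamples.

    Resamples are shared across edges (one resample -> one surrogate matrix).
    Edges touching a zero-variance region within a resample contribute a
    neutral r* = 0 to both tails for that resample (logged).
    """
    values = _subset_values(dataset, participant_subset)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants to bootstrap")
    p_regions = values.shape[1]
    rng = np.random.default_rng(config.seed)
    n_nonneg = np.zeros((p_regions, p_regions), dtype=np.int64)
    n_nonpos = np.zeros((p_regions, p_regions), dtype=np.int64)
    degenerate = 0
    for _ in range(config.n_boot):
        sample = values[rng.integers(0, n, size=n)]
        sd = sample.std(axis=0)
        if np.any(sd == 0):
            degenerate += 1
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(sample, rowvar=False)
            r = np.nan_to_num(r, nan=0.0)
        else:
            r = np.corrcoef(sample, rowvar=False)
        n_nonneg += r >= 0
        n_nonpos += r <= 0
    if degenerate:
        logger.warning(
            "%d/%d bootstrap resamples contained a zero-variance region; "
            "affected edges counted as r*=0", degenerate, config.n_boot,
        )
    p = 2.0 * np.minimum(n_nonneg, n_nonpos) / config.n_boot
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 0.0)
    return p


def bootstrap_mean_correlations(dataset, participant_subset,
                                config: BootstrapConfig) -> np.ndarray:
    """Off-diagonal mean correlation for each bootstrap resample (B-vector).

    Used to propagate within-window estimation uncertainty into trajectory
    confidence intervals: replicate b of every window, taken together across
    windows, forms one bootstrap replicate of the metric series.
    """
    values = _subset_values(dataset, participant_subset)
    n, p_regions = values.shape
    if n < 3:
        raise ValueError("need at least 3 participants to bootstrap")
    rng = np.random.default_rng(config.seed)
    iu = np.triu_indices(p_regions, 1)
    means = np.empty(config.n_boot)
    for b in range(config.n_boot):
        sample = values[rng.integers(0, n, size=n)]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sample, rowvar=False)
        means[b] = np.nan_to_num(r, nan=0.0)[iu].mean()
    return means


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values cannot be adjusted")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, p_adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return p_adj.reshape(p.shape)


def threshold_network(
    corr: CorrelationMatrix, p: np.ndarray, p_adj: np.ndarray, alpha: float
) -> ThresholdedNetwork:
    """Retain edges with FDR-adjusted p below ``alpha`` at their observed weight."""
    w = corr.weights
    if p_adj.shape != w.shape:
        raise ValueError("p_adj and correlation matrix dimensions differ")
    mask = p_adj < alpha
    np.fill_diagonal(mask, False)
    mask &= mask.T
    weights = np.where(mask, w, 0.0)
    iu = np.triu_indices(w.shape[0], 1)
    retained = w[iu][mask[iu]]
    return ThresholdedNetwork(
        weights=weights,
        mask=mask,
        p=p,
        p_adj=p_adj,
        n_positive=int((retained > 0).sum()),
        n_negative=int((retained < 0).sum()),
        provenance={"alpha": alpha, "n_participants": corr.n_participants},
    )


def build_thresholded_network(
    dataset, participant_subset, config: BootstrapConfig
) -> tuple[ThresholdedNetwork, CorrelationMatrix]:
    """Full pipeline for one subset: correlate, bootstrap, BH-adjust, threshold."""
    corr = correlation_matrix(dataset, participant_subset)
    p = bootstrap_edge_pvalues(dataset, participant_subset, config)
    iu = np.triu_indices(corr.n_regions, 1)
    p_adj = np.ones_like(p)
    p_adj[iu] = fdr_adjust(p[iu])
    p_adj.T[iu] = p_adj[iu]
    np.fill_diagonal(p_adj, 0.0)
    net = threshold_network(corr, p, p_adj, config.alpha)
    net.provenance.update({"n_boot": config.n_boot, "seed": config.seed})
    return net, corr
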