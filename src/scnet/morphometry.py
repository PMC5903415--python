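"""Regional morphometric rates and their association with network change.

Rates of cortical thinning (ΔCT, mm/year) and intracortical myelination
(ΔMT, percentage units/year, one map per cortical depth) are the slopes of
per-region ordinary least squares fits of the cross-sectional values on age.
Depth-resolved MT maps are treated as independent columns keyed by depth
label; the conventional main-analysis depth is 70% of cortical depth from the
pial surface. Associations with network change parameters (e.g. Δk_max) use
Spearman rank correlation, optionally with a spin-permutation p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import RegionSet
from .spin import SpinConfig, spin_pvalue

__all__ = ["regional_rates", "depth_profile_association"]


def regional_rates(values, ages) -> np.ndarray:
    """Per-region OLS slope of morphometry on age (cross-sectional rate)."""
    X = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    ages = np.asarray(ages, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; rates undefined")
    a = ages - ages.mean()
    return (a @ (X - X.mean(axis=0))) / (a @ a)


def depth_profile_association(
    mt_rates: dict[str, np.ndarray],
    target_map: np.ndarray,
    regions: RegionSet | None = None,
    spin_config: SpinConfig | None = None,
) -> pd.DataFrame:
    """Spearman rho of a network-change map against ΔMT at each cortical depth.

    Returns a table (depth, rho, p_spearman, p_perm); spin p-values are
    computed only when ``regions`` is given (the MT map is the rotated one).
    Missing/degenerate depth maps are skipped with a warning.
    """
    target_map = np.asarray(target_map, dtype=float)
    rows = []
    for depth, rates in mt_rates.items():
        if rates is None:
            warnings.warn(f"missing MT map at depth {depth!r}; skipped", stacklevel=2)
            continue
        rates = np.asarray(rates, dtype=float)
        if rates.shape != target_map.shape:
            warnings.warn(f"MT map at depth {depth!r} has wrong length; skipped",
                          stacklevel=2)
            continue
        rho, p_sp = stats.spearmanr(target_map, rates)
        p_perm = np.nan
        if regions is not None:
            result = spin_pvalue(target_map, rates, regions,
                                 spin_config or SpinConfig())
            p_perm = result.p_perm
        rows.append({"depth": depth, "rho": float(rho),
                     "p_spearman": float(p_sp), "p_perm": p_perm})
    return pd.DataFrame(rows)
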