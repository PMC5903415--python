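"""Overlapping age-defined participant windows.

Windows are defined in units of participant counts (not calendar age). Two
modes are provided:

``index``
    Participants are sorted by age and windows of ``width`` start every
    ``step`` participants; ``anchor_final`` appends a last window flush with
    the oldest participants when the regular grid does not reach them.

``stratum_interpolated`` (default)
    The age-sorted cohort is split into ``n_strata`` contiguous strata of
    near-equal size; windows are the strata themselves plus, for each adjacent
    pair, the older half of the first joined to the younger half of the second
    — yielding ``2 * n_strata - 1`` half-overlapping windows (9 for the
    canonical 5-strata design of ~60 participants per stratum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WindowingConfig", "WindowSpec", "make_windows", "window_median_ages"]


@dataclass
class WindowingConfig:
    width: int = 60
    step: int = 30
    mode: str = "stratum_interpolated"
    n_strata: int = 5
    anchor_final: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("index", "stratum_interpolated"):
            raise ValueError(f"unknown windowing mode {self.mode!r}")
        if self.mode == "index" and not (1 <= self.step <= self.width):
            raise ValueError("require 1 <= step <= width")


@dataclass
class WindowSpec:
    """One window: participant positions (sorted by age) and their median age."""

    indices: np.ndarray      # positions into the original participant order
    median_age: float
    window_index: int = 0

    @property
    def size(self) -> int:
        return len(self.indices)


def make_windows(ages, config: WindowingConfig | None = None) -> list[WindowSpec]:
    """Build ordered windows over a cohort; ties in age broken by input order."""
    if config is None:
        config = WindowingConfig()
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    order = np.argsort(ages, kind="stable")

    if config.mode == "index":
        if config.width > n:
            raise ValueError(f"window width {config.width} exceeds cohort size {n}")
        starts = list(range(0, n - config.width + 1, config.step))
        if config.anchor_final and starts[-1] + config.width < n:
            starts.append(n - config.width)
        member_lists = [order[s : s + config.width] for s in starts]
    else:
        k = config.n_strata
        if n < k:
            raise ValueError("fewer participants than strata")
        base, rem = divmod(n, k)
        sizes = [base + (1 if s < rem else 0) for s in range(k)]
        if max(sizes) - min(sizes) > 2:
            warnings.warn("strata sizes differ by more than 2", stacklevel=2)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        strata = [order[bounds[s] : bounds[s + 1]] for s in range(k)]
        member_lists = []
        for s in range(k):
            member_lists.append(strata[s])
            if s + 1 < k:
                # older half of stratum s + younger half of stratum s+1;
                # odd strata put their extra participant in the younger half
                m_a, m_b = sizes[s], sizes[s + 1]
                older = strata[s][m_a - m_a // 2 :]
                younger = strata[s + 1][: (m_b + 1) // 2]
                member_lists.append(np.concatenate([older, younger]))

    windows = [
        WindowSpec(indices=np.asarray(members), median_age=float(np.median(ages[members])))
        for members in member_lists
    ]
    windows.sort(key=lambda w: w.median_age)
    for i, w in enumerate(windows):
        w.window_index = i
    return windows


def window_median_ages(windows: list[WindowSpec]) -> np.ndarray:
    if not windows:
        raise ValueError("no windows supplied")
    return np.array([w.median_age for w in windows])
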