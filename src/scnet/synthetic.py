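"""Synthetic cortical cohorts with known ground truth.

The generator emulates the statistical structure a sliding-window structural
covariance analysis assumes: an adolescent cohort (default N = 297, ages 14-24,
five equal age strata), ~300 cortical regions laid out on two mirror-symmetric
hemispheric spheres, an inter-regional correlation matrix whose strength varies
smoothly (and non-monotonically) with age, spatially contiguous planted
modules, and linear-in-age regional thinning (CT) and myelination (MT) trends.

Each participant's regional vector is drawn from a multivariate normal whose
correlation matrix is the covariance model evaluated at that participant's own
age, so any windowing scheme can be applied downstream. The generating
parameters are returned as a :class:`GroundTruth` record so every recovery
target (age of minimum correlation, planted modules, regional slopes) can be
checked against what was actually planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import CorticalDataset, RegionSet

__all__ = [
    "CohortSpec",
    "CovarianceModel",
    "GroundTruth",
    "default_covariance_model",
    "generate_regions",
    "generate_cohort",
    "smooth_cortical_map",
    "MT_DEPTHS",
    "MAIN_MT_DEPTH",
]

BRAIN_RADIUS_MM = 70.0

# 10 fractional cortical depths (pial -> grey/white boundary) plus 2 absolute
# depths into white matter; the conventional main-analysis depth is 70%.
MT_DEPTHS: tuple[str, ...] = tuple(f"{10 * i}%" for i in range(1, 11)) + ("wm1mm", "wm2mm")
MAIN_MT_DEPTH = "70%"


@dataclass
class CohortSpec:
    """Sampling design of a synthetic cohort."""

    n_participants: int = 297
    age_range: tuple[float, float] = (14.0, 24.0)
    n_strata: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < self.n_strata:
            raise ValueError("need at least one participant per stratum")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")


@dataclass
class CovarianceModel:
    """Age-dependent block correlation model.

    ``within_module_r`` / ``between_module_r`` map age (years) to the pairwise
    Pearson correlation inside / between planted modules. The implied region x
    region correlation matrix must be positive semi-definite at every age;
    small violations are repaired by eigenvalue clipping at zero followed by
    re-normalization to unit diagonal.
    """

    within_module_r: Callable[[float], float]
    between_module_r: Callable[[float], float]
    age_of_minimum: float
    regional_noise_sd: float = 0.10
    psd_tol: float = 1e-8

    def correlation(self, age: float, module_labels: np.ndarray) -> np.ndarray:
        """Region x region correlation matrix at ``age`` for planted modules."""
        w = float(self.within_module_r(age))
        b = float(self.between_module_r(age))
        if not (-1.0 <= w <= 1.0 and -1.0 <= b <= 1.0):
            raise ValueError(f"model correlations outside [-1, 1] at age {age}")
        same = module_labels[:, None] == module_labels[None, :]
        corr = np.where(same, w, b)
        np.fill_diagonal(corr, 1.0)
        return _repair_psd(corr, self.psd_tol)


def default_covariance_model(
    a_star: float = 19.5,
    base_between: float = 0.18,
    curvature: float = 0.0045,
    module_contrast: float = 0.15,
    regional_noise_sd: float = 0.10,
) -> CovarianceModel:
    """Convex-in-age block model with its minimum at ``a_star`` years.

    Defaults are chosen so that windowed mean correlations run from roughly
    0.34 at age 14 down to 0.20 at the minimum — the same scale and shape as
    empirical adolescent cortical-thickness covariance — and so that bootstrap
    thresholding at n~60 retains many edges in young windows and few near the
    minimum, giving edge-density trajectories an interior minimum to recover.
    """

    def between(age: float) -> float:
        return base_between + curvature * (age - a_star) ** 2

    def within(age: float) -> float:
        return between(age) + module_contrast

    return CovarianceModel(
        within_module_r=within,
        between_module_r=between,
        age_of_minimum=a_star,
        regional_noise_sd=regional_noise_sd,
    )


@dataclass
class GroundTruth:
    """Generating parameters stored alongside each synthetic dataset."""

    age_of_minimum: float
    ct_slopes: np.ndarray                      # per-region, mm/year
    ct_baselines: np.ndarray                   # per-region, mm at age 14
    module_labels: np.ndarray                  # planted modules, 1-based
    mt_slopes: dict[str, np.ndarray] = field(default_factory=dict)  # PU/year
    model_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "age_of_minimum": self.age_of_minimum,
            "ct_slopes": np.asarray(self.ct_slopes).tolist(),
            "ct_baselines": np.asarray(self.ct_baselines).tolist(),
            "module_labels": np.asarray(self.module_labels).tolist(),
            "mt_slopes": {d: np.asarray(s).tolist() for d, s in self.mt_slopes.items()},
            "model_params": self.model_params,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            age_of_minimum=d["age_of_minimum"],
            ct_slopes=np.array(d["ct_slopes"]),
            ct_baselines=np.array(d["ct_baselines"]),
            module_labels=np.array(d["module_labels"], dtype=int),
            mt_slopes={k: np.array(v) for k, v in d["mt_slopes"].items()},
            model_params=d.get("model_params", {}),
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def generate_regions(n_regions: int, n_modules: int, seed: int) -> RegionSet:
    """Lay regions on two mirror-symmetric hemispheric spheres with planted modules.

    Half the regions go to each hemisphere, on a Fibonacci lattice covering the
    full projection sphere (as in surface-based pipelines, each hemisphere is
    inflated to its own sphere). Module labels are spatially contiguous: module
    seed regions are drawn at random on the left hemisphere and every region
    joins its nearest seed by great-circle distance (a spherical Voronoi
    patch); labels are mirrored to the right hemisphere so modules are
    bilateral. Centroids are the sphere coordinates scaled to a nominal brain
    radius, with hemispheres offset along x so homologous regions do not
    coincide in anatomical space.
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (half per hemisphere)")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    half = n_regions // 2
    if n_modules > half:
        raise ValueError("n_modules may not exceed n_regions / 2")

    rng = np.random.default_rng(seed)
    right = _fibonacci_sphere(half)
    left = right * np.array([-1.0, 1.0, 1.0])  # sagittal mirror

    seeds = rng.choice(half, size=n_modules, replace=False)
    # spherical Voronoi: nearest seed by great-circle distance == max dot product
    labels_half = np.argmax(left @ left[seeds].T, axis=1) + 1

    sphere = np.vstack([left, right])
    hemisphere = np.array(["left"] * half + ["right"] * half, dtype=object)
    offset = np.where(hemisphere == "left", -0.5, 0.5)[:, None] * np.array(
        [BRAIN_RADIUS_MM, 0.0, 0.0]
    )
    centroid = sphere * BRAIN_RADIUS_MM + offset
    module = np.concatenate([labels_half, labels_half])
    return RegionSet(hemisphere=hemisphere, centroid=centroid, sphere=sphere,
                     module=module)


def _real_spherical_harmonics(v: np.ndarray):
    """Real spherical harmonics of degrees 1-3 (orthonormal up to a common factor)."""
    x, y, z = v.T
    l1 = np.column_stack([x, y, z])
    l2 = np.column_stack([
        np.sqrt(3) * x * y, np.sqrt(3) * y * z, np.sqrt(3) * x * z,
        np.sqrt(3) / 2 * (x**2 - y**2), 0.5 * (3 * z**2 - 1),
    ])
    l3 = np.column_stack([
        0.5 * np.sqrt(5 / 2) * y * (3 * x**2 - y**2), np.sqrt(15) * x * y * z,
        0.5 * np.sqrt(3 / 2) * y * (5 * z**2 - 1), 0.5 * (5 * z**3 - 3 * z),
        0.5 * np.sqrt(3 / 2) * x * (5 * z**2 - 1),
        0.5 * np.sqrt(15) * z * (x**2 - y**2),
        0.5 * np.sqrt(5 / 2) * x * (x**2 - 3 * y**2),
    ])
    return l1, l2, l3


def smooth_cortical_map(regions: RegionSet, rng, noise: float = 0.25,
                        degree_weights: Sequence[float] = (1.0, 0.7, 0.5)) -> np.ndarray:
    """A bilaterally symmetric, spatially autocorrelated random regional map.

    A Gaussian random field with rotation-invariant covariance (independent
    equal-variance coefficients within each spherical-harmonic degree 1-3) is
    evaluated on the canonical hemisphere sphere, copied to each region's
    mirrored twin, and perturbed by regional white noise of ``noise`` times
    the field SD. Rotation invariance plus exact bilateral symmetry make such
    maps a valid smooth null for the mirrored-rotation spin test, while the
    noise floor gives them region-level granularity like empirical maps.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    right = np.flatnonzero(regions.hemisphere == "right")
    left = np.flatnonzero(regions.hemisphere == "left")
    field = np.zeros(len(right))
    for w, basis in zip(degree_weights,
                        _real_spherical_harmonics(regions.sphere[right])):
        field = field + w * (basis @ rng.standard_normal(basis.shape[1]))
    m = np.empty(regions.n_regions)
    m[right] = field
    m[left] = field  # left rows mirror right rows in construction order
    return m + noise * m.std() * rng.standard_normal(regions.n_regions)


def _repair_psd(corr: np.ndarray, tol: float) -> np.ndarray:
    """Clip negative eigenvalues at 0 and re-normalize to unit diagonal."""
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] >= -tol:
        if eigvals[0] < 0:  # numerically tiny negative: still repair
            pass
        else:
            return corr
    if eigvals[0] < -1e-2:
        raise ValueError(
            f"model correlation matrix far from PSD (min eigenvalue {eigvals[0]:.3g})"
        )
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _stratified_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Stratified-uniform ages: equal-length strata, near-equal counts."""
    lo, hi = spec.age_range
    edges = np.linspace(lo, hi, spec.n_strata + 1)
    base, rem = divmod(spec.n_participants, spec.n_strata)
    counts = [base + (1 if s < rem else 0) for s in range(spec.n_strata)]
    ages = np.concatenate(
        [rng.uniform(edges[s], edges[s + 1], size=counts[s])
         for s in range(spec.n_strata)]
    )
    return np.sort(ages)


def generate_cohort(
    spec: CohortSpec,
    regions: RegionSet,
    model: CovarianceModel | None = None,
    *,
    ct_baseline_mean: float = 2.7,
    ct_baseline_sd: float = 0.15,
    ct_slope_mean: float = -0.02,
    ct_slope_sd: float = 0.01,
    mt_depths: Sequence[str] = (),
    mt_slope_mean: float = 0.006,
    mt_slope_sd: float = 0.003,
    mt_coupling: tuple[np.ndarray, str, float] | None = None,
) -> tuple[CorticalDataset, GroundTruth]:
    """Draw a stratified cohort from the age-dependent correlation model.

    Each participant's CT vector is multivariate normal with correlation
    ``model.correlation(age, modules)``, per-region mean
    ``baseline + slope * (age - age_min_of_range)`` and marginal SD
    ``model.regional_noise_sd``. MT maps (one per entry of ``mt_depths``) are
    generated analogously with their own per-region slopes; ``mt_coupling``
    = (map, depth, strength) adds ``strength * standardized(map)`` to the MT
    slopes at one depth, planting a depth-specific association for recovery
    tests. Deterministic given ``spec.seed``.
    """
    if model is None:
        model = default_covariance_model()
    rng = np.random.default_rng(spec.seed)
    ages = _stratified_ages(spec, rng)
    n, p = spec.n_participants, regions.n_regions
    labels = regions.module
    if labels is None:
        labels = np.ones(p, dtype=int)

    ct_base = rng.normal(ct_baseline_mean, ct_baseline_sd, size=p)
    ct_slope = rng.normal(ct_slope_mean, ct_slope_sd, size=p)
    lo = spec.age_range[0]

    mt_slopes: dict[str, np.ndarray] = {}
    for depth in mt_depths:
        slope = rng.normal(mt_slope_mean, mt_slope_sd, size=p)
        if mt_coupling is not None and depth == mt_coupling[1]:
            cmap = np.asarray(mt_coupling[0], dtype=float)
            z = (cmap - cmap.mean()) / cmap.std()
            slope = slope + mt_coupling[2] * z
        mt_slopes[depth] = slope

    # One standardized draw per participant per map, correlated across regions
    # at that participant's age (Cholesky of the age-specific correlation).
    n_maps = 1 + len(mt_slopes)
    draws = np.empty((n_maps, n, p))
    for i, age in enumerate(ages):
        corr = model.correlation(age, labels)
        try:
            chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"correlation matrix at age {age:.2f} not PSD after repair"
            ) from exc
        draws[:, i, :] = rng.standard_normal((n_maps, p)) @ chol.T

    sd = model.regional_noise_sd
    ct = ct_base + np.outer(ages - lo, ct_slope) + sd * draws[0]

    participant_id = pd.Index([f"p{i:04d}" for i in range(n)], name="participant_id")
    region_id = pd.Index(regions.region_id, name="region_id")
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    mt_tables: dict[str, pd.DataFrame] = {}
    for k, (depth, slope) in enumerate(mt_slopes.items(), start=1):
        mt_vals = 1.0 + np.outer(ages - lo, slope) + 0.05 * draws[k]
        mt_tables[depth] = pd.DataFrame(mt_vals, index=participant_id,
                                        columns=region_id)

    dataset = CorticalDataset(
        values=pd.DataFrame(ct, index=participant_id, columns=region_id),
        participants=pd.DataFrame({"age": ages, "sex": sex}, index=participant_id),
        regions=regions.to_frame(),
        mt=mt_tables,
    )
    truth = GroundTruth(
        age_of_minimum=model.age_of_minimum,
        ct_slopes=ct_slope,
        ct_baselines=ct_base,
        module_labels=labels,
        mt_slopes=mt_slopes,
        model_params={
            "regional_noise_sd": model.regional_noise_sd,
            "n_participants": n,
            "age_range": list(spec.age_range),
            "n_strata": spec.n_strata,
            "seed": spec.seed,
        },
    )
    return dataset, truth
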