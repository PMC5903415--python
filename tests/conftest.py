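import numpy as np
import pytest

import scnet as s


@pytest.fixture(scope="session")
def regions100():
    return s.generate_regions(100, 4, seed=7)


@pytest.fixture(scope="session")
def regions60():
    return s.generate_regions(60, 2, seed=3)


@pytest.fixture(scope="session")
def cohort300(regions100):
    dataset, truth = s.generate_cohort(
        s.CohortSpec(n_participants=300, seed=1), regions100
    )
    return dataset, truth


@pytest.fixture(scope="session")
def window_ages():
    return np.linspace(14.5, 23.5, 9)


@pytest.fixture(scope="session")
def independent_cohort(regions100):
    """Cohort with uncorrelated regions but active age trends.

    Coverage-style checks on per-region OLS slopes need independent regions:
    with correlated regions the realized coverage fraction is heavy-tailed
    around its nominal level because all regions share the same draws.
    """
    model = constant_block_model(0.0, 0.0)
    dataset, truth = s.generate_cohort(
        s.CohortSpec(n_participants=300, seed=21), regions100, model
    )
    return dataset, truth


def make_equal_block_regions(n_regions: int, n_modules: int) -> s.RegionSet:
    """Regions on mirrored hemispheric spheres with equal-size planted blocks."""
    from scnet.synthetic import BRAIN_RADIUS_MM, _fibonacci_sphere

    half = n_regions // 2
    right = _fibonacci_sphere(half)
    sphere = np.vstack([right * np.array([-1.0, 1.0, 1.0]), right])
    hemisphere = np.array(["left"] * half + ["right"] * half, dtype=object)
    offset = np.where(hemisphere == "left", -0.5, 0.5)[:, None] * np.array(
        [BRAIN_RADIUS_MM, 0.0, 0.0]
    )
    centroid = sphere * BRAIN_RADIUS_MM + offset
    labels_half = 1 + (np.arange(half) * n_modules) // half
    module = np.tile(labels_half, 2)
    return s.RegionSet(hemisphere=hemisphere, centroid=centroid, sphere=sphere,
                       module=module)


def constant_block_model(within: float, between: float) -> s.CovarianceModel:
    return s.CovarianceModel(
        within_module_r=lambda a: within,
        between_module_r=lambda a: between,
        age_of_minimum=19.5,
    )
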