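"""Shared fixtures: small geometric masks and a reusable synthetic cohort."""

import numpy as np
import pytest

from segrobust import (
    BinaryMask,
    CohortConfig,
    ImageVolume,
    ObserverProfile,
    generate_cohort,
)


def mask_from(arr, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(arr, bool), spacing)


def ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    """Rasterized sphere: voxel centers within ``radius`` mm of ``center``."""
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return BinaryMask(r2 <= radius**2, spacing)


def small_cohort_config(n_patients=3, seed=0, noise_a=2.0, noise_b=4.0, bias_b=0.66):
    """A reduced cohort (smaller tumors and grid) for fast unit tests."""
    observers = tuple(
        [ObserverProfile(f"A{i}", "A", 1.0, noise_a) for i in range(3)]
        + [ObserverProfile(f"B{i}", "B", bias_b, noise_b) for i in range(3)]
    )
    return CohortConfig(
        n_patients=n_patients,
        observers=observers,
        tumor_volume_mean_cm3=12.0,
        tumor_volume_sd_cm3=3.0,
        native_spacing=(1.25, 1.25, 5.0),
        grid_shape=(64, 64, 16),
        master_seed=seed,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One full default-design cohort (21 patients, 6 observers)."""
    return generate_cohort(CohortConfig(master_seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
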