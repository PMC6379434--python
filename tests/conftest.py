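import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from msi3d.core import (
    CENTROID,
    PROFILE,
    GridMetadata,
    MassSpectrum,
    MsiDataset,
    PixelCoordinate,
)


@pytest.fixture
def tiny_grid():
    return GridMetadata(mz_range=(400.0, 1600.0))


@pytest.fixture
def centroid_dataset(tiny_grid):
    """2x2 centroid dataset with known content."""
    spectra = {
        PixelCoordinate(0, 0): MassSpectrum([500.0, 885.5], [1.0, 2.0]),
        PixelCoordinate(1, 0): MassSpectrum([500.2, 885.9], [3.0, 4.0]),
        PixelCoordinate(0, 1): MassSpectrum([600.0], [5.0]),
        PixelCoordinate(1, 1): MassSpectrum([700.0, 800.0], [6.0, 7.0]),
    }
    return MsiDataset(spectra=spectra, grid=tiny_grid, section_id="tiny")


def gaussian_profile(centers, heights, sigma=0.05, lo=400.0, hi=500.0, step=0.01,
                     baseline=None, noise_sd=0.0, seed=0):
    """Profile spectrum with Gaussian peaks, optional baseline and noise."""
    mz = np.arange(lo, hi, step)
    y = np.zeros_like(mz)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    if baseline is not None:
        y = y + baseline
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, mz.size)
    return MassSpectrum(mz, y, mode=PROFILE)


@pytest.fixture
def small_phantom_cfg():
    """Reduced phantom for fast end-to-end tests: 1 brain/group, 4 sections."""
    from msi3d.phantom import PhantomConfig

    return PhantomConfig(
        n_brains_per_group=1, sections_per_brain=4, grid_shape=(24, 18), seed=11
    )
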