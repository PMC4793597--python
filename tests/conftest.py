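"""Shared fixtures: small phantoms and their analyses, built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import ctoam
from ctoam.segmentation import BoneMask


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default two-ridge phantom, one patch per ridge, no noise."""
    spec = ctoam.PhantomSpec(seed=11)
    volume, truth = ctoam.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with 30 HU additive Gaussian noise."""
    spec = ctoam.PhantomSpec(seed=11, noise_sd=30.0)
    volume, truth = ctoam.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_phantom):
    _, volume, _ = noiseless_phantom
    return ctoam.analyse_volume(volume, subject_id="s1", side="left")


@pytest.fixture(scope="session")
def noisy_analysis(noisy_phantom):
    _, volume, _ = noisy_phantom
    return ctoam.analyse_volume(volume, subject_id="s1", side="left")


def random_masked_volume(rng: np.random.Generator, n: int | None = None):
    """A small random HU volume with a smooth random blob mask."""
    if n is None:
        n = int(rng.integers(8, 17))
    hu = rng.normal(300.0, 200.0, size=(n, n, n))
    blob = ndimage.gaussian_filter(rng.normal(size=(n, n, n)), 2) > 0
    while not blob.any():
        blob = ndimage.gaussian_filter(rng.normal(size=(n, n, n)), 2) > 0
    volume = ctoam.CtVolume(hu, (1.0, 1.0, 1.0))
    mask = BoneMask(blob, 0.0, "all", volume.spacing_mm, volume.axis_labels)
    return volume, mask


def axis_view(axis: int, pixel_size: float = 1.0) -> ctoam.ViewSpec:
    """Axis-aligned view whose image rows/cols are the two remaining axes in order."""
    e = np.eye(3)
    others = [a for a in range(3) if a != axis]
    return ctoam.ViewSpec(
        f"axis{axis}", tuple(e[axis]), tuple(e[others[1]]), tuple(e[others[0]]), pixel_size
    )
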