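"""Shared fixtures: all data is generated in-process, nothing is loaded."""

from __future__ import annotations

import numpy as np
import pytest

from leafspec import SyntheticConfig, generate_leaf_cube, generate_spectra


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_swir():
    """40 samples x 60 SWIR bands: cheap but structured."""
    cfg = SyntheticConfig(camera="SWIR", n_samples=40, n_bands=60, seed=1)
    sm, truth = generate_spectra(cfg)
    return sm, truth


@pytest.fixture(scope="session")
def small_cube():
    """One 60x80-pixel SWIR leaf scene with ground truth."""
    cfg = SyntheticConfig(camera="SWIR", n_bands=60, image_size=(60, 80), seed=3)
    return generate_leaf_cube(cfg)


@pytest.fixture(scope="session")
def default_swir():
    """The default study conditions: 193 samples x 204 SWIR bands, seed 42."""
    cfg = SyntheticConfig(camera="SWIR", seed=42)
    sm, truth = generate_spectra(cfg)
    return sm, truth
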