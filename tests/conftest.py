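import dataclasses

import numpy as np
import pytest

from meiboseg.phantom import PhantomConfig


@pytest.fixture
def clean_config():
    """Artifact-free phantom configuration (exact two-valued images)."""
    return PhantomConfig(
        blur_sigma=0.0,
        noise_sigma=0.0,
        specular_spot_count=0,
        illumination_gradient_strength=0.0,
        seed=42,
    )


@pytest.fixture
def default_config():
    """Default phantom configuration with mild artifacts."""
    return PhantomConfig(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def reseed(config, seed):
    return dataclasses.replace(config, seed=seed)


@pytest.fixture
def straight_bar_mask():
    """One straight vertical bar: rows 10..59, cols 26..34 (half-width 4)."""
    m = np.zeros((80, 64), dtype=bool)
    m[10:60, 26:35] = True
    return m
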