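"""Shared fixtures: small, fast phantoms generated at test time."""

import numpy as np
import pytest

from bowmetrics.phantom_sim import PhantomSpec, generate_stack


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, jitter-free single-frame phantom at default geometry."""
    return PhantomSpec(
        bowman_thickness_um=15.0, speckle_contrast=0.0, jitter_sd_px=0.0, n_frames=1, seed=11
    )


@pytest.fixture(scope="session")
def clean_capture(clean_spec):
    return generate_stack(clean_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Narrow field (just fits the 450 um window) to keep tests fast."""
    return PhantomSpec(
        bowman_thickness_um=15.0,
        lateral_extent_um=460.0,
        n_frames=4,
        seed=17,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
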