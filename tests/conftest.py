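"""Shared fixtures: synthetic strides at the study conditions."""

import numpy as np
import pytest

from stridetraj.simulate import SyntheticStrideSpec, simulate_stride


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, bias-free stride spec (exact forward model)."""
    return SyntheticStrideSpec(
        accel_noise_sd=0.0, gyro_noise_sd=0.0, gyro_bias=(0.0, 0.0, 0.0)
    )


@pytest.fixture(scope="session")
def clean_stride(clean_spec):
    """Noise-free recording plus its exact ground truth."""
    return simulate_stride(clean_spec)


@pytest.fixture(scope="session")
def noisy_stride():
    """Default (realistic-noise) recording plus ground truth."""
    return simulate_stride(SyntheticStrideSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
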