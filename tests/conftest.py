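import math

import numpy as np
import pytest

from ir2.phantom import DegradationSpec, PhantomSpec, degrade_volume, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom that still fits several (16, 64, 64) patches."""
    return PhantomSpec(grid_shape=(48, 160, 160), n_nuclei=120, seed=7)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return degrade_volume(generate_phantom(small_spec), DegradationSpec(seed=7))


@pytest.fixture(scope="session")
def clean_pair(small_spec):
    """Identity degradation: degraded channel equals the ground truth."""
    deg = DegradationSpec(
        blur_sigma0_um=0.0, blur_slope=0.0,
        attenuation_length_um=math.inf,
        gaussian_read_noise_sd=0.0, poisson_scale=0.0,
        channel_offset_voxels=(0, 0, 0), seed=7,
    )
    return degrade_volume(generate_phantom(small_spec), deg)


@pytest.fixture(scope="session")
def standard_pair():
    """The default-parameter phantom used for pipeline-level checks."""
    return degrade_volume(generate_phantom(PhantomSpec()), DegradationSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
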