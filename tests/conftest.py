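import numpy as np
import pytest

from conefuse import phantom as ph


@pytest.fixture(scope="session")
def small_shape():
    return (128, 192, 192)


@pytest.fixture(scope="session")
def small_voxel():
    return 0.1


@pytest.fixture(scope="session")
def small_specs(small_shape, small_voxel):
    return ph.default_three_cone_specs(small_shape, small_voxel, base_z=0.4)


@pytest.fixture(scope="session")
def clean_phantom(small_specs, small_shape, small_voxel):
    """Noiseless desk-scale phantom: 128x192x192 at 0.1 mm voxels."""
    return ph.generate_phantom_volume(small_specs, small_shape, small_voxel,
                                      noise_sigma=0.0, seed=42)


@pytest.fixture(scope="session")
def noisy_phantom(small_specs, small_shape, small_voxel):
    """Same phantom with 5%-of-contrast Gaussian noise."""
    return ph.generate_phantom_volume(small_specs, small_shape, small_voxel,
                                      noise_sigma=0.045, seed=42)
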