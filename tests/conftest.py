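import numpy as np
import pytest

from dermoknn import LesionSpec, generate_lesion_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def disk_spec():
    """A perfectly circular, noise- and hair-free lesion."""
    return LesionSpec(base_radius=40, asymmetry_level=0.0,
                      border_irregularity=0.0, hair_count=0, noise_sigma=0.0,
                      seed=7)


@pytest.fixture(scope="session")
def disk_case(disk_spec):
    return generate_lesion_image(disk_spec)


@pytest.fixture(scope="session")
def noisy_case():
    spec = LesionSpec(base_radius=30, asymmetry_level=0.2,
                      border_irregularity=0.15, hair_count=3, noise_sigma=4.0,
                      seed=11)
    return generate_lesion_image(spec)
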