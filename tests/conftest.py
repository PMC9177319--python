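import numpy as np
import pytest

from cornoct import (
    BScanImage,
    NoiseModel,
    SystemProfile,
    generate_phantom,
    make_geometry,
)


@pytest.fixture(scope="session")
def profile():
    return SystemProfile()


@pytest.fixture(scope="session")
def geometry(profile):
    return make_geometry(profile)


@pytest.fixture(scope="session")
def clean_phantom(profile, geometry):
    """Noise-free soft-edged phantom plus ground truth."""
    noise = NoiseModel(impulse_probability=0.0, speckle_scale=0.0, seed=0)
    return generate_phantom(profile, geometry, noise)


@pytest.fixture(scope="session")
def noisy_phantom(profile, geometry):
    """Phantom with speckle, impulse noise and a central bright line."""
    noise = NoiseModel(
        impulse_probability=0.1,
        speckle_scale=0.05,
        bright_line_column=180,
        bright_line_width=3,
        seed=7,
    )
    return generate_phantom(profile, geometry, noise)


@pytest.fixture
def constant_image(profile):
    return BScanImage(np.full((profile.rows, profile.cols), 60, dtype=np.uint8), profile)
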