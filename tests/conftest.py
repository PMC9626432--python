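import numpy as np
import pytest

from irtkit import CameraGeometry, PhantomSpec, generate_phantom

# Reduced test geometry: same optics, quarter-size frame, so registration
# tests stay fast while all physical conversions remain exercised.
SMALL_GEOMETRY = CameraGeometry(width_px=160, height_px=120)
FULL_GEOMETRY = CameraGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    return SMALL_GEOMETRY


@pytest.fixture(scope="session")
def full_geometry():
    return FULL_GEOMETRY


@pytest.fixture(scope="session")
def default_phantom():
    """Default-spec phantom at full frame size (seed 42)."""
    spec = PhantomSpec(seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(geometry=SMALL_GEOMETRY, seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free flat-body phantom on the small frame."""
    spec = PhantomSpec(geometry=SMALL_GEOMETRY, noise_sd=0.0, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def textured_phantom():
    """Noise-free phantom with smooth internal texture (registration food)."""
    spec = PhantomSpec(
        geometry=SMALL_GEOMETRY, noise_sd=0.0, texture_amp=1.5, seed=5
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
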