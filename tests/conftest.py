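import dataclasses

import numpy as np
import pytest

from surf2vol import PhantomParams, VolumeGrid, extract_surface, generate_patient_series


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    """A small, fast phantom configuration for unit tests (16x32x16)."""
    return PhantomParams(
        shape=(16, 32, 16),
        spacing=(8.0, 5.0, 6.0),
        body_semiaxes=(50.0, 60.0, 35.0),
        lung_semiaxes=(30.0, 25.0, 12.0),
        lung_offset=(0.0, 4.0, 18.0),
        tumor_center=(0.0, 4.0, 18.0),
        tumor_radius=8.0,
        motion_amplitude=8.0,
        spine_offset=-32.0,
        spine_radius=6.0,
        noise_sigma=10.0,
    )


@pytest.fixture(scope="session")
def tiny_series(tiny_params):
    return generate_patient_series(tiny_params, 4, seed=5)


@pytest.fixture(scope="session")
def desk_params() -> PhantomParams:
    """The default study conditions (40x64x40)."""
    return PhantomParams()


def digitized_surface(fn, shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0)):
    """Voxelize an implicit solid ``fn(z, y, x) -> bool`` and extract its shell."""
    axes = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)]
    z, y, x = np.meshgrid(*axes, indexing="ij")
    vol = VolumeGrid(np.where(fn(z, y, x), 50.0, -1000.0).astype(np.float32), spacing)
    return extract_surface(vol)


@pytest.fixture(scope="session")
def sphere_surface():
    return digitized_surface(lambda z, y, x: z**2 + y**2 + x**2 <= 20.0**2)


@pytest.fixture(scope="session")
def ellipsoid_surface():
    return digitized_surface(
        lambda z, y, x: (z / 22.0) ** 2 + (y / 11.0) ** 2 + (x / 11.0) ** 2 <= 1.0
    )
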