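import numpy as np
import pytest

import metalsim as ms


@pytest.fixture(scope="session")
def spectrum120():
    return ms.generate_spectrum(120.0)


@pytest.fixture(scope="session")
def water():
    return ms.load_material("water")


@pytest.fixture(scope="session")
def titanium():
    return ms.load_material("titanium")


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def small_geometry():
    """Small parallel-beam geometry for fast projector tests."""
    return ms.AcquisitionGeometry.parallel(
        fov_mm=128.0, n_views=180, det_pitch_mm=1.0, n_rows=1
    )


@pytest.fixture(scope="session")
def disc_volume():
    """Uniform disc, radius 100 mm, mu = 0.2 /cm, on a 256^2 grid of 1 mm voxels."""
    n = 256
    c = (np.arange(n) - 0.5 * (n - 1))
    X, Y = np.meshgrid(c, c, indexing="xy")
    mu = np.where(X**2 + Y**2 <= 100.0**2, 0.2, 0.0)[None]
    return ms.VoxelVolume(mu, (1.0, 1.0, 1.0), is_hu=False)


@pytest.fixture(scope="session")
def disc_geometry():
    return ms.AcquisitionGeometry.parallel(
        fov_mm=256.0, n_views=360, det_pitch_mm=1.0, n_rows=1
    )


@pytest.fixture(scope="session")
def axial_rod():
    """12.7-mm titanium rod extruded along z (the validation-rod analog)."""
    return ms.make_rod_object(12.7, 60.0, "titanium", voxel_mm=0.5, orientation=(0.0, 90.0))
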