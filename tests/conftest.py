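import numpy as np
import pytest

from trabkit.phantoms import PhantomSpec, make_plate_phantom
from trabkit.segmentation import BinaryVOI
from trabkit.voi import sphere_mask


def as_binary_voi(bone: np.ndarray, voxel_mm: float) -> BinaryVOI:
    """Wrap a binary cube as a segmented VOI with its inscribed-sphere mask."""
    bone = bone.astype(bool)
    n = bone.shape[0]
    mask = sphere_mask(n)
    return BinaryVOI(bone & mask, mask, voxel_mm, threshold_used=0.0,
                     bone_cube=bone)


@pytest.fixture(scope="session")
def plate64():
    """64³ plate phantom with whole slabs: t = 0.2, s = 0.44 mm at 0.02 mm."""
    spec = PhantomSpec("plates", (64, 64, 64), 0.02,
                       plate_thickness_mm=0.2, plate_spacing_mm=0.44)
    vol, gt = make_plate_phantom(spec)
    return as_binary_voi(vol.values, 0.02), gt


@pytest.fixture(scope="session")
def ball96():
    """Voxel-centred solid ball, radius 30 voxels in a 96³ cube (0.02 mm)."""
    n = 96
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = n // 2
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= 30 ** 2
    return as_binary_voi(ball, 0.02)


@pytest.fixture(scope="session")
def torus96():
    """Voxelized torus (major 24, minor 8 voxels) inside a 96³ cube."""
    n = 96
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = n // 2
    rad = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    torus = (rad - 24) ** 2 + (zz - c) ** 2 <= 8 ** 2
    return as_binary_voi(torus, 0.02)
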