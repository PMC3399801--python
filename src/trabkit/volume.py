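"""Core spatial containers: grayscale volumes and triangulated surfaces.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` with ``z`` the proximodistal (slice) axis,
matching a transverse CT stack acquired shaft-to-head.  All physical lengths
are millimetres; voxels are isotropic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import trimesh

__all__ = ["VolumeImage", "SurfaceMesh", "read_volume", "write_volume"]

# axis order of the array: index 0 = z (proximodistal), 1 = y, 2 = x
AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class VolumeImage:
    """A 3D scalar image with isotropic voxel size.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Scalar intensities (grayscale or binary).
    voxel_mm : float
        Isotropic voxel edge length in mm.
    origin_mm : ndarray of 3 floats
        Physical position (z, y, x) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    voxel_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along (z, y, x) in mm."""
        return np.array(self.shape) * self.voxel_mm

    def index_of(self, point_mm) -> np.ndarray:
        """Nearest voxel index of a physical (z, y, x) point."""
        rel = (np.asarray(point_mm, dtype=float) - self.origin_mm) / self.voxel_mm
        return np.rint(rel).astype(int)

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.values.copy(), self.voxel_mm, self.origin_mm.copy())


@dataclass
class SurfaceMesh:
    """Triangulated surface with vertices in mm, (x, y, z) coordinate columns."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.triangles.ndim != 2 or self.triangles.shape[0] < 1:
            raise ValueError("mesh must contain at least one triangle")
        if self.triangles.max() >= len(self.vertices) or self.triangles.min() < 0:
            raise ValueError("triangle indices out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def area(self) -> float:
        return float(self.to_trimesh().area)

    def translated(self, offset) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, float), self.triangles)

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        m = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))

    def save(self, path) -> None:
        self.to_trimesh().export(str(path))


def write_volume(vol: VolumeImage, path) -> None:
    """Write a volume as multi-page TIFF (.tif) or MetaImage (.mha)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, vol.values)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"voxel_mm": vol.voxel_mm,
                                       "origin_mm": vol.origin_mm.tolist()}))
    elif path.suffix.lower() == ".mha":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.values)
        img.SetSpacing((vol.voxel_mm,) * 3)
        img.SetOrigin(tuple(vol.origin_mm[::-1]))  # sitk origin is (x, y, z)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path, voxel_mm: float | None = None) -> VolumeImage:
    """Read a TIFF stack (voxel size from sidecar or argument) or MetaImage."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        origin = np.zeros(3)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            voxel_mm = voxel_mm or meta["voxel_mm"]
            origin = np.asarray(meta.get("origin_mm", origin))
        if voxel_mm is None:
            raise ValueError("voxel_mm required for TIFF without sidecar")
        return VolumeImage(values, voxel_mm, origin)
    if path.suffix.lower() == ".mha":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if not np.allclose(spacing, spacing[0], rtol=1e-6):
            raise ValueError("anisotropic voxels are not supported")
        return VolumeImage(sitk.GetArrayFromImage(img), spacing[0],
                           np.asarray(img.GetOrigin())[::-1])
    raise ValueError(f"unsupported volume format: {path.suffix}")
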