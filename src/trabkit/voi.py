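"""Joint-scaled volume-of-interest placement.

The protocol: bound the articular surface with an axis-aligned box, put the
VOI centre at the box centre, set the cube edge to 1/6 of the proximodistal
(z) height of the articular surface, and measure everything on the sphere
inscribed in that cube to avoid corner effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import SurfaceMesh, VolumeImage

__all__ = ["Box", "VOISpec", "VOIVolume", "articular_bounding_box",
           "voi_spec_from_surface", "extract_spherical_voi", "check_continuum"]

#: joint-height divisor for the cube edge
EDGE_FRACTION = 1.0 / 6.0


@dataclass
class Box:
    """Axis-aligned bounding box; ``min_mm``/``max_mm`` are (x, y, z) vectors."""

    min_mm: np.ndarray
    max_mm: np.ndarray

    @property
    def center_mm(self) -> np.ndarray:
        return (self.min_mm + self.max_mm) / 2.0

    @property
    def size_mm(self) -> np.ndarray:
        return self.max_mm - self.min_mm


@dataclass
class VOISpec:
    """Sphere-in-cube measurement region: centre (x, y, z) in mm, cube edge in mm."""

    center_mm: np.ndarray
    cube_edge_mm: float

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if not self.cube_edge_mm > 0:
            raise ValueError("cube_edge_mm must be positive")

    @property
    def sphere_diameter_mm(self) -> float:
        return self.cube_edge_mm


@dataclass
class VOIVolume:
    """Cubic crop plus the inscribed-sphere mask; statistics use masked voxels only."""

    values: np.ndarray
    mask: np.ndarray
    voxel_mm: float
    spec: VOISpec | None = None

    @property
    def sphere_volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_mm ** 3


def articular_bounding_box(mesh: SurfaceMesh) -> Box:
    """Extremes of the articular-surface vertices along the three axes."""
    if len(mesh.vertices) == 0:
        raise ValueError("empty mesh")
    return Box(mesh.vertices.min(axis=0), mesh.vertices.max(axis=0))


def voi_spec_from_surface(mesh: SurfaceMesh) -> VOISpec:
    """Centre at the bounding-box midpoint; edge = proximodistal height / 6."""
    box = articular_bounding_box(mesh)
    z_height = box.size_mm[2]
    if z_height <= 0:
        raise ValueError("articular surface has zero proximodistal extent")
    return VOISpec(box.center_mm, z_height * EDGE_FRACTION)


def sphere_mask(n: int) -> np.ndarray:
    """Boolean inscribed-sphere mask for an n³ cube (voxel-centre sampling)."""
    c = (n - 1) / 2.0
    zz, yy, xx = np.ogrid[:n, :n, :n]
    r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
    return r2 <= (n / 2.0) ** 2


def extract_spherical_voi(vol: VolumeImage, spec: VOISpec) -> VOIVolume:
    """Crop the cube around ``spec.center_mm`` and build the inscribed-sphere mask.

    The cube is snapped to the voxel grid with an odd edge count so the
    centre voxel is defined.  Raises if the cube does not fit in the volume.
    """
    n = int(np.rint(spec.cube_edge_mm / vol.voxel_mm))
    n += (n + 1) % 2  # nearest odd count
    if n < 3:
        raise ValueError("VOI smaller than 3 voxels across")
    # spec centre is (x, y, z); array indexing is (z, y, x)
    center_zyx = spec.center_mm[::-1]
    ci = vol.index_of(center_zyx)
    half = n // 2
    lo = ci - half
    hi = ci + half + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(vol.shape)):
        raise ValueError(
            f"VOI cube of {n} voxels at index {ci.tolist()} exceeds volume "
            f"bounds {vol.shape}; choose a smaller VOI or a larger scan")
    crop = vol.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return VOIVolume(np.ascontiguousarray(crop), sphere_mask(n), vol.voxel_mm, spec)


def check_continuum(spec: VOISpec, mean_intertrabecular_mm: float,
                    minimum: float = 3.0) -> tuple[bool, float]:
    """Continuum-assumption check: the sphere must span ≥ 3 intertrabecular lengths.

    ``mean_intertrabecular_mm`` is typically Tb.Th + Tb.Sp.  Returns
    ``(passed, count)``; the minimum count is inclusive.
    """
    if mean_intertrabecular_mm <= 0:
        raise ValueError("mean_intertrabecular_mm must be positive")
    count = spec.sphere_diameter_mm / mean_intertrabecular_mm
    return count >= minimum, count
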