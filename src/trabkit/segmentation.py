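"""Isodata (Ridler–Calvard) thresholding and binary clean-up.

The threshold is computed from the grayscale values inside the spherical
mask only, then applied to the whole VOI; the same threshold feeds every
downstream morphometric operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .voi import VOIVolume

__all__ = ["BinaryVOI", "isodata_threshold", "binarize", "purge"]

# dual connectivity: 26 for foreground, 6 for background (avoids Euler paradoxes)
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class BinaryVOI:
    """Segmented VOI: ``bone`` is restricted to the spherical mask.

    ``bone_cube`` keeps the unmasked cubic segmentation; structural
    operators (thickness, skeleton, iso-surface) use it so trabeculae are
    not artificially truncated at the spherical boundary, while every
    average and count stays restricted to the mask.
    """

    bone: np.ndarray
    mask: np.ndarray
    voxel_mm: float
    threshold_used: float
    bone_cube: np.ndarray | None = None

    @property
    def bone_fraction(self) -> float:
        return float(self.bone.sum()) / float(self.mask.sum())

    @property
    def sphere_volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_mm ** 3


def isodata_threshold(voi: VOIVolume, tol: float = 0.5,
                      max_iter: int = 100) -> float:
    """Ridler–Calvard fixed point: T ← (mean below T + mean above T) / 2.

    Iterated from the global (masked) mean until the update is below ``tol``
    intensity units.  Only voxels inside the sphere mask contribute.
    """
    vals = np.asarray(voi.values, dtype=float)[voi.mask]
    if np.unique(vals).size < 2:
        raise ValueError("constant image inside the mask: no threshold exists")
    t = float(vals.mean())
    for _ in range(max_iter):
        below = vals[vals < t]
        above = vals[vals >= t]
        if below.size == 0 or above.size == 0:
            break
        t_new = (below.mean() + above.mean()) / 2.0
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def binarize(voi: VOIVolume, threshold: float) -> BinaryVOI:
    """Bone = (value ≥ threshold) within the sphere mask."""
    cube = np.asarray(voi.values, dtype=float) >= threshold
    bone = cube & voi.mask
    if not bone.any():
        warnings.warn("threshold above maximum intensity: empty bone phase")
    return BinaryVOI(bone, voi.mask, voi.voxel_mm, float(threshold), cube)


def purge(b: BinaryVOI) -> BinaryVOI:
    """Keep the largest 26-connected bone component and fill enclosed cavities.

    Cavities are 6-connected background components with no voxel outside the
    sphere mask (marrow connected to the VOI boundary is genuine background).
    Required before Euler-based connectivity, which presumes a single
    component with no enclosed voids.
    """
    bone = np.asarray(b.bone, dtype=bool)
    if not bone.any():
        warnings.warn("purge called on empty bone phase")
        return BinaryVOI(bone.copy(), b.mask, b.voxel_mm, b.threshold_used)
    labels, n = ndimage.label(bone, structure=STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        bone = labels == (int(np.argmax(sizes)) + 1)
    else:
        bone = bone.copy()
    bg_labels, n_bg = ndimage.label(~bone, structure=STRUCT_6)
    outside = np.unique(bg_labels[~b.mask])
    cavity = ~np.isin(bg_labels, outside) & ~bone
    bone |= cavity
    return BinaryVOI(bone & b.mask, b.mask, b.voxel_mm, b.threshold_used)
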