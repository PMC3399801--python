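"""Model-independent trabecular morphometry on a segmented spherical VOI.

Operators
---------
``bvtv``                bone volume fraction (voxel counting)
``local_thickness``     distance-transform sphere-fitting thickness map;
                        volume-weighted mean gives Tb.Th (bone phase) or
                        Tb.Sp (marrow phase)
``tb_n``                inverse mean spacing between trabecular mid-axes
``euler_connectivity``  Euler characteristic → connectivity density
``smi``                 structure model index by infinitesimal surface dilation
``mil_fabric``          mean-intercept-length fabric tensor → degree of anisotropy
``summarize``           the full suite for one VOI

Structural computations (distance transforms, skeletons, iso-surfaces) run
on the unmasked cubic crop so that trabeculae are not artificially cut by
the spherical boundary; all averages and counts are restricted to the
inscribed sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .segmentation import BinaryVOI, purge
from .voi import sphere_mask

__all__ = ["MorphometryConfig", "FabricTensor", "MorphometrySummary",
           "bvtv", "local_thickness", "tb_n", "euler_connectivity",
           "smi", "mil_fabric", "summarize"]


@dataclass
class MorphometryConfig:
    """Tunable numerical parameters of the morphometric operators.

    ``n_directions`` and ``line_spacing_factor`` (× voxel) control the MIL
    sampling; ``eps_factor`` (× voxel) is the SMI dilation step;
    ``smi_smooth_sigma`` (voxels) is the Gaussian pre-smoothing applied
    before iso-surfacing to suppress voxel staircase artefacts;
    ``purge_before_connd`` removes islands/cavities before the Euler count.
    """

    n_directions: int = 128
    line_spacing_factor: float = 2.0
    eps_factor: float = 0.5
    smi_smooth_sigma: float = 1.0
    purge_before_connd: bool = True
    thickness_levels: int = 48
    seed: int = 0


@dataclass
class FabricTensor:
    """MIL ellipsoid fit: eigenvalues are mean intercept lengths (mm), descending."""

    matrix: np.ndarray            # the quadric A with 1/MIL²(ω) = ωᵀAω
    mil: np.ndarray               # (mil1 ≥ mil2 ≥ mil3), mm
    eigenvectors: np.ndarray      # columns match ``mil`` entries, (x, y, z)
    n_directions_used: int

    @property
    def da(self) -> float:
        return float(self.mil[0] / self.mil[2])

    @property
    def minor_axis(self) -> np.ndarray:
        """Direction of the smallest mean intercept length (plate normal)."""
        return self.eigenvectors[:, 2]


@dataclass
class MorphometrySummary:
    """One specimen's trabecular suite plus provenance."""

    bvtv: float
    tb_th_mm: float
    tb_th_corr_mm: float
    tb_sp_mm: float
    tb_n_per_mm: float
    conn_d_per_mm3: float
    smi: float
    da: float
    voxel_mm: float
    threshold: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("bvtv", "tb_th_mm", "tb_th_corr_mm", "tb_sp_mm", "tb_n_per_mm",
              "conn_d_per_mm3", "smi", "da", "voxel_mm", "threshold")}
        return d


def _cube_bone(b: BinaryVOI) -> np.ndarray:
    """Unmasked cubic segmentation if available, else the masked bone."""
    cube = getattr(b, "bone_cube", None)
    return np.asarray(cube if cube is not None else b.bone, dtype=bool)


def bvtv(b: BinaryVOI) -> float:
    """Bone voxels / sphere voxels."""
    frac = b.bone_fraction
    if frac == 0:
        warnings.warn("empty bone phase: BV/TV = 0")
    return frac


def local_thickness(b: BinaryVOI, phase: str = "bone",
                    max_levels: int = 48) -> tuple[float, np.ndarray]:
    """Sphere-fitting local thickness; returns (mean_mm over phase∩mask, map_mm).

    The thickness at a point is the diameter of the largest sphere that
    contains the point and fits entirely within the phase.  Computed by
    sweeping distance-transform level sets from the largest inscribed-sphere
    radius downward: a voxel within distance r of some point whose own
    distance map is ≥ r lies in a sphere of radius r.
    """
    cube = _cube_bone(b)
    phase_arr = cube if phase == "bone" else ~cube
    if not phase_arr.any():
        raise ValueError(f"{phase} phase is empty")
    th = _thickness_map(phase_arr, max_levels)
    sel = phase_arr & b.mask
    if not sel.any():
        raise ValueError(f"{phase} phase is empty inside the sphere mask")
    return float(th[sel].mean()) * b.voxel_mm, th * b.voxel_mm


def _bounded_edt(phase: np.ndarray) -> np.ndarray:
    """Distance map treating everything beyond the crop as background."""
    padded = np.pad(phase, 1, mode="constant", constant_values=0)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]


def _thickness_map(phase: np.ndarray, max_levels: int) -> np.ndarray:
    """Local thickness in voxel units (see :func:`local_thickness`)."""
    edt = _bounded_edt(phase)
    radii = np.unique(edt[phase])
    if radii.size == 0 or radii[-1] == 0:
        return np.zeros(phase.shape)
    if radii.size > max_levels:
        idx = np.unique(np.linspace(0, radii.size - 1, max_levels).round().astype(int))
        radii = radii[idx]
    th = np.zeros(phase.shape)
    for r in radii[::-1]:
        centers = edt >= r
        reach = ndimage.distance_transform_edt(~centers)
        newly = (reach <= r) & phase & (th == 0)
        th[newly] = 2.0 * r
    return th


def _distance_ridge(phase: np.ndarray) -> np.ndarray:
    """Mid-axis voxels: plateau local maxima of the Euclidean distance map.

    Unlike curve skeletonization this keeps medial *surfaces* for plate-like
    structures (a thinning skeleton collapses an unbounded plate to a point,
    destroying the mid-axis spacing).
    """
    edt = _bounded_edt(phase)
    ridge = (edt >= ndimage.maximum_filter(edt, size=3)) & phase
    return ridge


def tb_n(b: BinaryVOI, max_levels: int = 48) -> float:
    """Trabecular number: inverse of the mean spacing between mid-axes (1/mm).

    Mid-axes are the distance-transform ridge of the bone phase; their
    spacing is the sphere-fitting local thickness of the non-axis space
    (1.5 voxels added back for the finite ridge width).  Exact on parallel
    plates, whose mid-surfaces sit one period apart.
    """
    cube = _cube_bone(b)
    if not (cube & b.mask).any():
        raise ValueError("bone phase is empty")
    ridge = _distance_ridge(cube)
    if not ridge.any():
        warnings.warn("empty mid-axis set; single blob spans the VOI")
        n = b.mask.shape[0]
        return 1.0 / (n * b.voxel_mm)
    th = _thickness_map(~ridge, max_levels)
    sel = ~ridge & b.mask
    spacing_mm = (float(th[sel].mean()) + 1.5) * b.voxel_mm
    return 1.0 / spacing_mm


def euler_connectivity(b: BinaryVOI) -> tuple[int, float]:
    """Euler characteristic χ (26-connectivity) and Conn.D = β₁ / sphere volume.

    Assumes a purged input (single component, no enclosed cavities), for
    which β₁ = 1 − χ.  Multi-component input is reported with a warning.
    """
    bone = np.asarray(b.bone, dtype=bool)
    if not bone.any():
        warnings.warn("empty bone phase: connectivity 0")
        return 1, 0.0
    _, n_comp = ndimage.label(bone, structure=np.ones((3, 3, 3)))
    if n_comp > 1:
        warnings.warn(f"{n_comp} components present; purge before Conn.D")
    chi = int(measure.euler_number(bone, connectivity=3))
    beta1 = n_comp - chi  # β₂ assumed 0 after cavity filling
    return chi, float(beta1) / b.sphere_volume_mm3


def _marching_surface(cube: np.ndarray, voxel_mm: float, smooth_sigma: float,
                      pad: int = 4):
    """Iso-surface of the (edge-padded, smoothed) binary cube at level 0.5."""
    padded = np.pad(cube.astype(float), pad, mode="edge")
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    verts, faces, normals, _ = measure.marching_cubes(padded, 0.5)
    verts = (verts - pad) * voxel_mm
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return verts, faces, normals / norms


def _triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def smi(b: BinaryVOI, dilation_eps_mm: float | None = None,
        smooth_sigma: float = 1.0) -> float:
    """Structure model index: SMI = 6·S′·V/S² with S′ = dS/dε under dilation.

    The bone surface is triangulated at the 0.5 iso-level of the smoothed
    binary cube; each vertex is displaced by ε along its outward normal and
    the area derivative is estimated by the forward difference.  Only
    triangles whose centroids lie inside the measurement sphere contribute,
    so structures spanning the VOI are treated as unbounded (their cut rims
    carry no area).  ≈ 0 for plates, 3 for rods, 4 for spheres.
    """
    eps = dilation_eps_mm if dilation_eps_mm is not None else 0.5 * b.voxel_mm
    if eps <= 0 or eps > b.voxel_mm:
        raise ValueError("dilation_eps_mm must lie in (0, voxel_mm]")
    cube = _cube_bone(b)
    if not (cube & b.mask).any():
        raise ValueError("bone surface is empty")
    verts, faces, normals, = _marching_surface(cube, b.voxel_mm, smooth_sigma)
    n_vox = b.mask.shape[0]
    center = np.full(3, (n_vox - 1) / 2.0) * b.voxel_mm
    r_keep = (n_vox / 2.0 - 1.0) * b.voxel_mm
    centroids = verts[faces].mean(axis=1)
    keep = np.linalg.norm(centroids - center, axis=1) <= r_keep
    if not keep.any():
        raise ValueError("no surface inside the measurement sphere")
    faces = faces[keep]
    s0 = float(_triangle_areas(verts, faces).sum())
    # outward = direction in which the smoothed indicator decreases
    outward = -normals if _normals_point_inward(cube, verts, normals, b.voxel_mm) else normals
    s1 = float(_triangle_areas(verts + eps * outward, faces).sum())
    v = float((cube & b.mask).sum()) * b.voxel_mm ** 3
    s_prime = (s1 - s0) / eps
    return 6.0 * s_prime * v / s0 ** 2


def _normals_point_inward(cube, verts, normals, voxel_mm, delta_vox=1.5):
    """True if marching-cubes normals point into the bone phase."""
    probe = (verts + delta_vox * voxel_mm * normals) / voxel_mm
    vals = ndimage.map_coordinates(cube.astype(np.float32), probe.T,
                                   order=1, mode="nearest")
    return float(vals.mean()) > 0.5


def _hemisphere_directions(n: int, seed: int) -> np.ndarray:
    """Quasi-uniform hemisphere directions (Fibonacci), randomly rotated (seeded)."""
    i = np.arange(n) + 0.5
    z = i / n                      # upper hemisphere
    phi = np.pi * (1 + 5 ** 0.5) * i
    s = np.sqrt(1 - z ** 2)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return dirs @ q.T


def mil_fabric(b: BinaryVOI, n_directions: int = 128,
               line_spacing_mm: float | None = None, seed: int = 0,
               step_vox: float = 1.0) -> FabricTensor:
    """Mean-intercept-length fabric tensor on the spherical VOI.

    For each test direction, parallel lines at ``line_spacing_mm`` are laid
    through the sphere; bone/background interface crossings are counted and
    MIL(ω) = intercepted length / crossings.  The ellipsoid
    1/MIL²(ω) = ωᵀAω is fitted by least squares; fabric eigenvalues are
    1/√eig(A) and DA = mil1/mil3.  Directions with no crossings are dropped
    (plate-parallel lines legitimately see no interfaces); more than 20 %
    dropped aborts.
    """
    if n_directions < 64:
        raise ValueError("n_directions must be at least 64")
    bone = np.asarray(b.bone, dtype=np.uint8)
    mask = b.mask
    if not bone.any() or not (mask & ~bone.astype(bool)).any():
        raise ValueError("MIL requires both phases inside the mask")
    n = mask.shape[0]
    c = (n - 1) / 2.0
    radius = n / 2.0
    spacing_vox = ((line_spacing_mm / b.voxel_mm)
                   if line_spacing_mm is not None else 2.0)
    dirs = _hemisphere_directions(n_directions, seed)

    offs = np.arange(-radius, radius + spacing_vox, spacing_vox)
    oa, ob = np.meshgrid(offs, offs, indexing="ij")
    disk = oa ** 2 + ob ** 2 <= radius ** 2
    oa, ob = oa[disk], ob[disk]
    ts = np.arange(-radius, radius + step_vox, step_vox)

    mils, kept_dirs = [], []
    dropped = 0
    for w in dirs:
        u = np.cross(w, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(w, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        # points: (lines, steps, zyx); directions are (x, y, z) so flip
        base = oa[:, None, None] * u[::-1] + ob[:, None, None] * v[::-1]
        pts = c + base + ts[None, :, None] * w[::-1]
        flat = pts.reshape(-1, 3).T
        bone_s = ndimage.map_coordinates(bone, flat, order=0, mode="constant",
                                         cval=0).reshape(len(oa), len(ts))
        mask_s = ndimage.map_coordinates(mask.astype(np.uint8), flat, order=0,
                                         mode="constant", cval=0
                                         ).reshape(len(oa), len(ts)).astype(bool)
        pair_in = mask_s[:, 1:] & mask_s[:, :-1]
        crossings = int((pair_in & (bone_s[:, 1:] != bone_s[:, :-1])).sum())
        length = float(pair_in.sum()) * step_vox * b.voxel_mm
        if crossings == 0:
            dropped += 1
            continue
        # a mean intercept cannot exceed the sphere diameter
        mils.append(min(length / crossings, n * b.voxel_mm))
        kept_dirs.append(w)
    if dropped > 0.2 * n_directions:
        raise ValueError(f"{dropped}/{n_directions} directions had no "
                         "interface crossings; structure too sparse for MIL")
    if dropped:
        warnings.warn(f"dropped {dropped} MIL directions with no crossings")

    W = np.asarray(kept_dirs)
    q = 1.0 / np.asarray(mils) ** 2
    x, y, z = W[:, 0], W[:, 1], W[:, 2]
    design = np.column_stack([x * x, y * y, z * z,
                              2 * x * y, 2 * x * z, 2 * y * z])
    coef, *_ = np.linalg.lstsq(design, q, rcond=None)
    A = np.array([[coef[0], coef[3], coef[4]],
                  [coef[3], coef[1], coef[5]],
                  [coef[4], coef[5], coef[2]]])
    evals, evecs = np.linalg.eigh(A)
    # near-degenerate fits (ideal plates: in-plane MIL at the diameter cap)
    # are floored at the diameter bound to keep the tensor positive definite
    evals = np.maximum(evals, 1.0 / (n * b.voxel_mm) ** 2)
    mil_vals = 1.0 / np.sqrt(evals)         # ascending evals → descending MIL
    order = np.argsort(mil_vals)[::-1]
    return FabricTensor(A, mil_vals[order], evecs[:, order], len(kept_dirs))


def summarize(voi, config: MorphometryConfig | None = None,
              correction_model=None) -> MorphometrySummary:
    """Run the full morphometric suite on a grayscale VOI.

    Thresholds with isodata, binarizes, and computes every variable; Tb.Th
    is additionally voxel-size corrected with ``correction_model`` (the
    published default model when None).  Failures in individual operators
    yield NaN for that variable and are recorded in the provenance log.
    """
    from .resolution import DEFAULT_CORRECTION, correct_tbth
    from .segmentation import binarize, isodata_threshold

    cfg = config or MorphometryConfig()
    model = correction_model or DEFAULT_CORRECTION
    threshold = isodata_threshold(voi)
    b = binarize(voi, threshold)
    prov = {"threshold": threshold, "n_directions": cfg.n_directions,
            "eps_mm": cfg.eps_factor * b.voxel_mm, "seed": cfg.seed,
            "errors": {}}
    out = dict.fromkeys(
        ["bvtv", "tb_th_mm", "tb_th_corr_mm", "tb_sp_mm", "tb_n_per_mm",
         "conn_d_per_mm3", "smi", "da"], float("nan"))

    def stage(name, fn):
        try:
            out[name] = fn()
        except Exception as exc:  # record and continue with NaN
            prov["errors"][name] = f"{type(exc).__name__}: {exc}"

    stage("bvtv", lambda: bvtv(b))
    stage("tb_th_mm", lambda: local_thickness(b, "bone", cfg.thickness_levels)[0])
    stage("tb_sp_mm", lambda: local_thickness(b, "background",
                                              cfg.thickness_levels)[0])
    stage("tb_n_per_mm", lambda: tb_n(b, cfg.thickness_levels))
    stage("conn_d_per_mm3", lambda: euler_connectivity(
        purge(b) if cfg.purge_before_connd else b)[1])
    stage("smi", lambda: smi(b, cfg.eps_factor * b.voxel_mm,
                             cfg.smi_smooth_sigma))
    stage("da", lambda: mil_fabric(
        b, cfg.n_directions,
        cfg.line_spacing_factor * b.voxel_mm, cfg.seed).da)
    if np.isfinite(out["tb_th_mm"]):
        out["tb_th_corr_mm"] = correct_tbth(out["tb_th_mm"], b.voxel_mm, model)
    return MorphometrySummary(voxel_mm=b.voxel_mm, threshold=threshold,
                              provenance=prov, **out)
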