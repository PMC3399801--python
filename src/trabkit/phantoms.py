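"""Synthetic trabecular phantoms and statistical fixtures.

Every input the analysis chain consumes can be generated here with known
ground truth: binary plate/rod/Gaussian-random-field phantoms for the
morphometric operators, grayscale degradation emulating a CT point-spread
function and detector noise, hemispherical articular caps for the VOI
protocol, Brownian-motion tip traits on a phylogeny, and group-structured
multivariate-normal feature tables for the discriminant stage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import AXIS_INDEX, SurfaceMesh, VolumeImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_plate_phantom",
    "make_rod_phantom",
    "make_isotropic_phantom",
    "degrade",
    "make_joint_mesh",
    "simulate_bm_traits",
    "simulate_groups",
]

#: grayscale plateau intensities used by :func:`degrade` (8-bit-like scale);
#: fixed so that isodata thresholds on noise-free phantoms are predictable.
FOREGROUND_INTENSITY = 190.0
BACKGROUND_INTENSITY = 60.0


@dataclass
class PhantomSpec:
    """Geometric recipe for a synthetic trabecular volume.

    ``kind`` selects the family: parallel ``plates`` (SMI ≈ 0), a square
    lattice of ``rods`` (SMI ≈ 3), or an ``isotropic`` thresholded Gaussian
    random field (DA ≈ 1).  Lengths in mm.
    """

    kind: str
    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 0.02
    plate_thickness_mm: float | None = None
    plate_spacing_mm: float | None = None
    rod_radius_mm: float | None = None
    pitch_mm: float | None = None
    target_bvtv: float | None = None
    correlation_length_mm: float | None = None
    orientation_axis: str = "z"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"plates", "rods", "isotropic"}:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be positive")
        if min(self.shape) < 32:
            raise ValueError("shape must be at least 32 voxels per axis")
        if self.orientation_axis not in AXIS_INDEX:
            raise ValueError("orientation_axis must be one of x, y, z")
        for name in ("plate_thickness_mm", "plate_spacing_mm",
                     "rod_radius_mm", "pitch_mm", "correlation_length_mm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive")
        if self.target_bvtv is not None and not 0 < self.target_bvtv < 1:
            raise ValueError("target_bvtv must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Analytic morphometry of a phantom; the oracle every operator is tested against."""

    bvtv: float | None = None
    tb_th_mm: float | None = None
    tb_sp_mm: float | None = None
    tb_n_per_mm: float | None = None
    conn_per_volume: float | None = None
    expected_smi: float | None = None
    da_lower_bound: float | None = None
    normal_axis: str | None = None


def _axis_coordinate(shape, axis_idx):
    """Voxel-centre coordinate (in voxels) along one axis, broadcast to the grid."""
    n = shape[axis_idx]
    coord = np.arange(n) + 0.5
    expand = [None] * 3
    expand[axis_idx] = slice(None)
    return coord[tuple(expand)]


def make_plate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, GroundTruth]:
    """Parallel slabs of thickness t separated by s, normal to ``orientation_axis``.

    Analytically BV/TV = t/(t+s), Tb.Th = t, Tb.Sp = s, Tb.N = 1/(t+s).
    """
    if spec.kind != "plates":
        raise ValueError("spec.kind must be 'plates'")
    t, s = spec.plate_thickness_mm, spec.plate_spacing_mm
    if t is None or s is None:
        raise ValueError("plate phantom needs plate_thickness_mm and plate_spacing_mm")
    period_vox = (t + s) / spec.voxel_mm
    if period_vox < 3:
        raise ValueError("plate period smaller than 3 voxels is unresolvable")
    axis = AXIS_INDEX[spec.orientation_axis]
    if t + s > spec.shape[axis] * spec.voxel_mm:
        raise ValueError("plate period exceeds volume extent")
    coord = _axis_coordinate(spec.shape, axis) * spec.voxel_mm
    phase = np.mod(coord, t + s)
    bone = np.broadcast_to(phase < t, spec.shape).astype(np.uint8)
    gt = GroundTruth(
        bvtv=t / (t + s), tb_th_mm=t, tb_sp_mm=s, tb_n_per_mm=1.0 / (t + s),
        expected_smi=0.0, da_lower_bound=2.0, normal_axis=spec.orientation_axis,
    )
    return VolumeImage(np.ascontiguousarray(bone), spec.voxel_mm), gt


def make_rod_phantom(spec: PhantomSpec) -> tuple[VolumeImage, GroundTruth]:
    """Square lattice of parallel cylinders along ``orientation_axis``.

    Tb.Th = 2r, lattice density 1/pitch along either transverse axis,
    BV/TV = πr²/pitch², SMI ≈ 3.
    """
    if spec.kind != "rods":
        raise ValueError("spec.kind must be 'rods'")
    r, p = spec.rod_radius_mm, spec.pitch_mm
    if r is None or p is None:
        raise ValueError("rod phantom needs rod_radius_mm and pitch_mm")
    if 2 * r / spec.voxel_mm < 3:
        raise ValueError("rod diameter smaller than 3 voxels is unresolvable")
    if 2 * r > p:
        raise ValueError("rods overlap: diameter exceeds pitch")
    axis = AXIS_INDEX[spec.orientation_axis]
    trans = [i for i in range(3) if i != axis]
    u = _axis_coordinate(spec.shape, trans[0]) * spec.voxel_mm
    v = _axis_coordinate(spec.shape, trans[1]) * spec.voxel_mm
    # distance (in the transverse plane) to the nearest lattice point; the
    # lattice is phased so rod axes pass through voxel centres, which keeps
    # the discretized cross-section symmetric
    half_vox = spec.voxel_mm / 2.0
    du = np.abs(np.mod(u - half_vox, p) - p / 2)
    dv = np.abs(np.mod(v - half_vox, p) - p / 2)
    bone = (du ** 2 + dv ** 2 <= r ** 2)
    bone = np.broadcast_to(bone, spec.shape).astype(np.uint8)
    gt = GroundTruth(
        bvtv=np.pi * r ** 2 / p ** 2, tb_th_mm=2 * r, tb_n_per_mm=1.0 / p,
        expected_smi=3.0, normal_axis=None,
    )
    return VolumeImage(np.ascontiguousarray(bone), spec.voxel_mm), gt


def make_isotropic_phantom(spec: PhantomSpec,
                           axis_ratio: float = 1.0) -> tuple[VolumeImage, GroundTruth]:
    """Thresholded smoothed Gaussian random field with prescribed BV/TV.

    The threshold is the (1 − BV/TV) quantile of the field, so the realised
    bone fraction matches ``target_bvtv`` to within quantisation.  With
    ``axis_ratio`` > 1 the smoothing kernel is stretched along
    ``orientation_axis``, producing an anisotropic control structure.
    """
    if spec.kind != "isotropic":
        raise ValueError("spec.kind must be 'isotropic'")
    if spec.target_bvtv is None or not 0.05 < spec.target_bvtv < 0.95:
        raise ValueError("target_bvtv must lie in (0.05, 0.95)")
    corr = spec.correlation_length_mm or 8 * spec.voxel_mm
    sigma_vox = corr / spec.voxel_mm / 2.0
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.shape)
    sigmas = np.full(3, sigma_vox)
    if axis_ratio != 1.0:
        sigmas[AXIS_INDEX[spec.orientation_axis]] *= axis_ratio
    # wrap mode keeps the field statistics homogeneous up to the boundary
    f = ndimage.gaussian_filter(noise, sigmas, mode="wrap")
    thr = np.quantile(f, 1.0 - spec.target_bvtv)
    bone = (f >= thr).astype(np.uint8)
    gt = GroundTruth(bvtv=spec.target_bvtv,
                     da_lower_bound=1.3 if axis_ratio != 1.0 else None,
                     normal_axis=None)
    return VolumeImage(bone, spec.voxel_mm), gt


def degrade(vol: VolumeImage, blur_sigma_mm: float = 0.0,
            noise_sd: float = 0.0, seed: int = 0) -> VolumeImage:
    """Turn a binary phantom into a grayscale scan.

    Foreground/background plateaus at 190/60, Gaussian blur emulating the
    scanner point-spread function (partial-volume effect), then additive
    Gaussian noise.  Deterministic given ``seed``.
    """
    if blur_sigma_mm < 0 or noise_sd < 0:
        raise ValueError("blur_sigma_mm and noise_sd must be non-negative")
    gray = np.where(vol.values > 0, FOREGROUND_INTENSITY, BACKGROUND_INTENSITY)
    if blur_sigma_mm > 0:
        gray = ndimage.gaussian_filter(gray, blur_sigma_mm / vol.voxel_mm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sd, gray.shape)
    return VolumeImage(gray, vol.voxel_mm, vol.origin_mm.copy())


def make_joint_mesh(head_radius_mm: float, coverage_fraction: float = 1.0,
                    n_theta: int = 64, n_phi: int = 128) -> SurfaceMesh:
    """Spherical-cap stand-in for a manually selected articular surface.

    The cap is centred on the origin with its apex on +z (proximal);
    ``coverage_fraction`` is the cap area as a fraction of a full hemisphere
    (2πr²).  Cap area = 2πr²h/r with h the cap height, so h = r·coverage.
    """
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    r = head_radius_mm
    h = r * coverage_fraction
    theta_max = np.arccos(1 - h / r)  # polar angle from +z
    thetas = np.linspace(0, theta_max, n_theta + 1)[1:]
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)

    verts = [np.array([0.0, 0.0, r])]  # apex
    rows = []
    for th in thetas:
        start = len(verts)
        for ph in phis:
            verts.append(np.array([r * np.sin(th) * np.cos(ph),
                                   r * np.sin(th) * np.sin(ph),
                                   r * np.cos(th)]))
        rows.append(start)
    tris = []
    for j in range(n_phi):  # fan around the apex
        tris.append([0, rows[0] + j, rows[0] + (j + 1) % n_phi])
    for i in range(len(rows) - 1):
        a, b = rows[i], rows[i + 1]
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            tris.append([a + j, b + j, b + jn])
            tris.append([a + j, b + jn, a + jn])
    return SurfaceMesh(np.asarray(verts), np.asarray(tris))


def bm_covariance_matrix(tree) -> pd.DataFrame:
    """Convenience re-export; see :func:`trabkit.phylo.bm_covariance`."""
    from .phylo import bm_covariance

    return bm_covariance(tree)


def simulate_bm_traits(tree, sigma2: float, root_value: float = 0.0,
                       seed: int = 0, n_traits: int = 1) -> pd.DataFrame:
    """Brownian-motion tip traits: one MVN draw with covariance σ²·C(tree).

    Returns a (tips × traits) DataFrame.  Non-ultrametric trees are allowed;
    zero-length terminal branches only trigger a warning (tips then duplicate
    their parent's state up to the shared covariance).
    """
    from .phylo import bm_covariance, tip_labels

    labels = tip_labels(tree)
    if len(labels) < 3:
        raise ValueError("Brownian simulation requires at least 3 tips")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    C = bm_covariance(tree).loc[labels, labels].to_numpy()
    if np.any(np.diag(C) <= 0):
        warnings.warn("tree has zero root-to-tip depth for some tips")
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        draws = np.full((len(labels), n_traits), root_value)
    else:
        # Cholesky with a tiny jitter guard for zero-length terminal branches
        try:
            L = np.linalg.cholesky(sigma2 * C)
        except np.linalg.LinAlgError:
            warnings.warn("singular BM covariance; adding jitter")
            L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(len(labels)))
        draws = root_value + L @ rng.standard_normal((len(labels), n_traits))
    return pd.DataFrame(draws, index=labels,
                        columns=[f"trait_{i}" for i in range(n_traits)])


def locomotor_demo_centroids(effect_sd: float = 2.5,
                             variables: list[str] | None = None) -> pd.DataFrame:
    """Seven-group centroid layout for discriminant recovery experiments.

    Groups are placed on a balanced incomplete design where every pair of
    groups differs by ``effect_sd`` pooled standard deviations in at least
    two of the five variables (minimum centroid separation effect_sd·√2).
    """
    from .allometry import LOCOMOTOR_GROUPS

    cols = variables or ["conn_d", "smi", "tb_n", "tb_th", "da"]
    design = np.array([[0, 0, 0, 0, 0],
                       [1, 1, 0, 0, 0],
                       [1, 0, 1, 0, 0],
                       [0, 1, 0, 1, 0],
                       [0, 0, 1, 1, 0],
                       [1, 0, 0, 1, 1],
                       [0, 1, 1, 0, 1]], dtype=float)
    return pd.DataFrame(design * effect_sd, index=LOCOMOTOR_GROUPS,
                        columns=cols)


def simulate_groups(centroids: pd.DataFrame, pooled_cov: np.ndarray,
                    n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """Labelled MVN draws sharing one within-group covariance (the LDA model).

    ``centroids`` is a (groups × variables) DataFrame; the returned table has
    the same variable columns plus a ``group`` column.
    """
    cov = np.asarray(pooled_cov, dtype=float)
    p = centroids.shape[1]
    if cov.shape != (p, p) or not np.allclose(cov, cov.T):
        raise ValueError("pooled_cov must be symmetric (p × p)")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError("pooled_cov must be positive definite")
    rng = np.random.default_rng(seed)
    frames = []
    for g, mu in centroids.iterrows():
        x = rng.multivariate_normal(mu.to_numpy(), cov, size=n_per_group,
                                    method="cholesky")
        df = pd.DataFrame(x, columns=centroids.columns)
        df.insert(0, "group", g)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
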