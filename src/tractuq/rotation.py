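"""Rotation of SH-coefficient images.

A naive spatial rotation of an SH image moves voxels but leaves each
voxel's angular profile pointing the old way, which breaks the coupling
between fiber orientation and the signal. Augmentation here therefore
applies the same 3D rotation twice: to the voxel grid (resampling) and,
per voxel, to the SH coefficient vector through the block-diagonal rotation
operator of the real basis (one orthogonal block per even degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from . import shbasis
from .core import SHVolume
from .errors import ShapeError

#: axis order for the Euler angles: extrinsic rotations about x, then y, then z
AXIS_ORDER = "xyz-extrinsic"


@dataclass
class RotationSpec:
    """Three extrinsic Euler angles in degrees about the grid axes x, y, z."""

    angles: tuple[float, float, float]
    order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.shape != (3,) or not np.all(np.isfinite(a)):
            raise ValueError("angles must be 3 finite scalars (degrees)")
        self.angles = tuple(a.tolist())

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 rotation matrix R (x applied first, then y, then z)."""
        return Rotation.from_euler("xyz", self.angles, degrees=True).as_matrix()

    @property
    def is_identity(self) -> bool:
        return all(a == 0.0 for a in self.angles)


@dataclass
class SHRotationOperator:
    """Block-diagonal rotation of real even-degree SH coefficients."""

    blocks: dict[int, np.ndarray]  # degree l -> (2l+1, 2l+1) orthogonal block
    lmax: int = field(default=0)

    def __post_init__(self) -> None:
        if self.blocks:
            self.lmax = max(self.blocks)

    @property
    def n_coeffs(self) -> int:
        return shbasis.n_coeffs(self.lmax)

    def as_matrix(self) -> np.ndarray:
        """Dense (M, M) block-diagonal matrix."""
        m = self.n_coeffs
        out = np.zeros((m, m))
        for l, sl in shbasis.degree_slices(self.lmax).items():
            out[sl, sl] = self.blocks[l]
        return out


# fixed, well-spread evaluation directions for the change-of-frame solve
_FIT_DIRECTIONS = None


def _fit_directions(n: int = 120) -> np.ndarray:
    global _FIT_DIRECTIONS
    if _FIT_DIRECTIONS is None or _FIT_DIRECTIONS.shape[0] < n:
        _FIT_DIRECTIONS = fibonacci_sphere(n)
    return _FIT_DIRECTIONS[:n]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_sh_rotation(rot: RotationSpec, lmax: int) -> SHRotationOperator:
    """Construct the real-SH rotation operator for a spatial rotation R.

    For each even degree l the block D_l satisfies, for every unit u,
    ``Y_l(u) @ D_l = Y_l(R^{-1} u)`` so that coefficients c' = D_l c
    synthesize the rotated function f'(u) = f(R^{-1} u). Because the
    degree-l subspace is rotation-invariant, solving this linear system on
    a fixed over-determined set of directions is exact to floating-point
    precision; no recursion over Wigner matrices is needed.
    """
    if lmax % 2 != 0 or lmax < 0:
        raise ShapeError("lmax must be even and non-negative")
    r_inv = rot.matrix.T
    u = _fit_directions(max(60, 6 * (2 * lmax + 1)))
    design = shbasis.design_matrix(u, lmax)
    design_rot = shbasis.design_matrix(u @ r_inv.T, lmax)
    blocks: dict[int, np.ndarray] = {0: np.eye(1)}
    for l, sl in shbasis.degree_slices(lmax).items():
        if l == 0:
            continue
        d, *_ = np.linalg.lstsq(design[:, sl], design_rot[:, sl], rcond=None)
        blocks[l] = d
    return SHRotationOperator(blocks, lmax)


def rotate_sh_coeffs(coeffs: np.ndarray, op: SHRotationOperator) -> np.ndarray:
    """Apply the block-diagonal SH rotation to one or many coefficient vectors.

    Accepts an (..., M) array; each degree block acts on its own slice, so
    the per-degree Euclidean norm is preserved.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.shape[-1] != op.n_coeffs:
        raise ShapeError(
            f"coefficient length {c.shape[-1]} does not match operator "
            f"lmax={op.lmax} (expected {op.n_coeffs})"
        )
    out = np.empty_like(c)
    for l, sl in shbasis.degree_slices(op.lmax).items():
        out[..., sl] = c[..., sl] @ op.blocks[l].T
    return out


def compose(a: SHRotationOperator, b: SHRotationOperator) -> SHRotationOperator:
    """Operator for 'apply b, then a' (matrix product per degree)."""
    if a.lmax != b.lmax:
        raise ShapeError("operators have different lmax")
    return SHRotationOperator({l: a.blocks[l] @ b.blocks[l] for l in a.blocks}, a.lmax)


def _world_rotation_as_voxel_affine(
    shape: tuple[int, int, int], affine: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space (matrix, offset) pulling input values onto the rotated grid.

    The rotation is about the volume center in world coordinates; the
    returned pair feeds scipy's affine_transform, which maps output voxel
    v to input voxel ``matrix @ v + offset``.
    """
    a3 = affine[:3, :3]
    t = affine[:3, 3]
    center_vox = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    center_world = a3 @ center_vox + t
    a3_inv = np.linalg.inv(a3)
    r_inv = r.T
    matrix = a3_inv @ r_inv @ a3
    offset = a3_inv @ (r_inv @ (t - center_world) + center_world - t)
    return matrix, offset


def resample_rotated(
    data: np.ndarray, affine: np.ndarray, rot: RotationSpec, order: int = 1
) -> np.ndarray:
    """Spatially rotate a 3D (or channel-last 4D) grid about its center.

    order=1 gives trilinear interpolation (coefficients, probabilities),
    order=0 nearest-neighbor (label masks). Out-of-bounds regions are
    zero-filled.
    """
    if rot.is_identity:
        return data.copy()
    r = rot.matrix
    shape3 = data.shape[:3]
    matrix, offset = _world_rotation_as_voxel_affine(shape3, affine, r)
    if data.ndim == 3:
        return ndimage.affine_transform(
            data.astype(float), matrix, offset=offset, order=order,
            mode="grid-constant",
        )
    out = np.empty_like(data, dtype=float)
    for ch in range(data.shape[3]):
        out[..., ch] = ndimage.affine_transform(
            data[..., ch].astype(float), matrix, offset=offset, order=order,
            mode="grid-constant",
        )
    return out


def rotate_volume_and_sh(
    sh: SHVolume,
    masks: np.ndarray | None,
    rot: RotationSpec,
) -> tuple[SHVolume, np.ndarray | None]:
    """Rotate grid and per-voxel SH coefficients by the same rotation.

    Coefficient channels are resampled with trilinear interpolation, masks
    (3D or channel-last 4D boolean) with nearest-neighbor; every resampled
    coefficient vector is then multiplied by the SH rotation operator so
    angular profiles follow the grid.
    """
    if masks is not None and masks.shape[:3] != sh.spatial_shape:
        raise ShapeError("mask grid does not match SH volume")
    if rot.is_identity:
        return (
            SHVolume(sh.coeffs.copy(), sh.lmax, sh.affine, sh.basis),
            None if masks is None else masks.copy(),
        )
    coeffs = resample_rotated(sh.coeffs, sh.affine, rot, order=1)
    op = build_sh_rotation(rot, sh.lmax)
    coeffs = rotate_sh_coeffs(coeffs, op)
    out_masks = None
    if masks is not None:
        out_masks = resample_rotated(
            masks.astype(float), sh.affine, rot, order=0
        ) > 0.5
    return SHVolume(coeffs, sh.lmax, sh.affine, sh.basis), out_masks


def sample_rotation(range_deg: float, rng: np.random.Generator) -> RotationSpec:
    """Draw three i.i.d. uniform angles on [-range_deg, +range_deg] degrees."""
    if range_deg < 0:
        raise ValueError("rotation range must be non-negative")
    if range_deg == 0:
        return RotationSpec((0.0, 0.0, 0.0))
    angles = rng.uniform(-range_deg, range_deg, size=3)
    return RotationSpec(tuple(angles.tolist()))
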