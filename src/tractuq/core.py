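"""Core data containers shared by every pipeline stage.

All volumes carry a 4x4 voxel-to-world affine (NIfTI convention, mm).
Gradient tables follow the FSL layout: one b-value per frame and one unit
direction per non-b0 frame; b0 frames keep a zero direction vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, FormatError, ShapeError

#: frames with b-value at or below this (s/mm^2) are treated as b0
DEFAULT_B0_THRESHOLD = 50.0

#: identifier of the SH convention used throughout: real basis, even degrees
#: only, descriptive ordering l=0,2,...,lmax with m=-l..l, orthonormal.
REAL_SH_BASIS = "real-even-descriptive"


@dataclass
class GradientTable:
    """Diffusion gradient scheme: unit directions and b-values (s/mm^2)."""

    directions: np.ndarray  # (G, 3)
    bvalues: np.ndarray  # (G,)
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ShapeError(f"directions must be (G, 3), got {self.directions.shape}")
        if self.bvalues.shape != (self.directions.shape[0],):
            raise FormatError(
                f"{self.bvalues.shape[0]} b-values for "
                f"{self.directions.shape[0]} directions"
            )
        norms = np.linalg.norm(self.directions[~self.b0_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise DataError("non-b0 gradient directions must have unit norm")

    @property
    def n(self) -> int:
        return self.bvalues.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues <= self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def subset(self, idx: np.ndarray) -> "GradientTable":
        return GradientTable(
            self.directions[idx], self.bvalues[idx], self.b0_threshold
        )


@dataclass
class DWIVolume:
    """4D diffusion-weighted image plus its gradient table."""

    data: np.ndarray  # (X, Y, Z, G), non-negative
    affine: np.ndarray  # (4, 4)
    gradients: GradientTable
    brain_mask: np.ndarray | None = None  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ShapeError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != self.gradients.n:
            raise FormatError(
                f"image has {self.data.shape[3]} frames but gradient table "
                f"has {self.gradients.n} entries"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("DWI data contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise DataError("affine is singular")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3, |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class SHVolume:
    """4D grid of real even-degree SH coefficients, one vector per voxel."""

    coeffs: np.ndarray  # (X, Y, Z, M)
    lmax: int
    affine: np.ndarray
    basis: str = REAL_SH_BASIS

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.lmax % 2 != 0 or self.lmax < 0:
            raise ShapeError("lmax must be even and non-negative")
        m = (self.lmax + 1) * (self.lmax + 2) // 2
        if self.coeffs.ndim != 4 or self.coeffs.shape[3] != m:
            raise ShapeError(
                f"expected {m} coefficient channels for lmax={self.lmax}, "
                f"got shape {self.coeffs.shape}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise DataError("SH coefficients contain non-finite values")

    @property
    def n_coeffs(self) -> int:
        return self.coeffs.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class BrainMask:
    """Binary intracranial mask on the same grid as the volume it masks."""

    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ShapeError("brain mask must be 3D")


@dataclass
class TractMaskSet:
    """Multi-label binary tract masks: one channel per tract, overlaps allowed."""

    data: np.ndarray  # (X, Y, Z, N) bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ShapeError("tract masks must be (X, Y, Z, N)")
        if self.names is not None and len(self.names) != self.data.shape[3]:
            raise ShapeError("one name per tract channel required")

    @property
    def n_tracts(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))
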