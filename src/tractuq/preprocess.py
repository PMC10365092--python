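"""DWI preprocessing: shell selection, b0 normalization, SH projection,
outlier clamping, and clinical-quality degradation (gradient reordering and
truncation).

The projection onto even-degree real spherical harmonics is a plain linear
least-squares fit per voxel — no diffusion model is fitted. Fitting on the
b0-normalized single shell makes the coefficients comparable across
subjects and scanners.
"""

from __future__ import annotations

import logging
import warnings

import nibabel as nib
import numpy as np

from . import shbasis
from .core import DEFAULT_B0_THRESHOLD, BrainMask, DWIVolume, GradientTable, SHVolume
from .errors import (
    ConditioningError,
    DataError,
    FormatError,
    SelectionError,
    ShapeError,
)

logger = logging.getLogger(__name__)


def read_dwi(
    image_path,
    bval_path,
    bvec_path,
    mask_path=None,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> DWIVolume:
    """Load a 4D NIfTI plus FSL-style bval/bvec text files.

    bvec files hold 3 rows of G whitespace-separated numbers; non-b0
    directions are re-normalized to unit length, b0 directions are left as
    zero vectors.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    bvals = np.loadtxt(str(bval_path), ndmin=1, dtype=float)
    bvecs = np.loadtxt(str(bvec_path), ndmin=2, dtype=float)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: rows are x/y/z components
    g = data.shape[3]
    if bvals.shape[0] != g:
        raise FormatError(f"{bval_path}: {bvals.shape[0]} b-values for {g} frames")
    if bvecs.shape[0] != g:
        raise FormatError(f"{bvec_path}: {bvecs.shape[0]} directions for {g} frames")
    if not np.all(np.isfinite(data)):
        raise DataError(f"{image_path}: non-finite voxel values")
    # unit-normalize the diffusion-weighted directions only
    bvecs = bvecs.copy()
    dw = bvals > b0_threshold
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms < 1e-12):
        raise DataError(f"{bvec_path}: zero direction on a diffusion-weighted frame")
    bvecs[dw] /= norms[:, None]
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    gtab = GradientTable(bvecs, bvals, b0_threshold)
    return DWIVolume(data, np.asarray(img.affine), gtab, brain_mask=mask)


def extract_shell(
    dwi: DWIVolume, b_target: float, tolerance: float = 100.0
) -> tuple[DWIVolume, DWIVolume]:
    """Split a multi-shell acquisition into one shell and its b0 frames.

    Returns ``(shell, b0s)`` where the shell holds exactly the frames with
    ``|b - b_target| <= tolerance`` and b0s holds all frames at or below
    the table's b0 threshold, both in acquisition order.
    """
    bvals = dwi.gradients.bvalues
    shell_idx = np.where(np.abs(bvals - b_target) <= tolerance)[0]
    b0_idx = np.where(dwi.gradients.b0_mask)[0]
    if shell_idx.size == 0:
        raise SelectionError(
            f"no frames within {tolerance} of b={b_target}; "
            f"available b-values: {sorted(set(bvals.tolist()))}"
        )
    if b0_idx.size == 0:
        raise SelectionError(
            f"no b0 frames (threshold {dwi.gradients.b0_threshold}); "
            f"available b-values: {sorted(set(bvals.tolist()))}"
        )
    shell = DWIVolume(
        dwi.data[..., shell_idx],
        dwi.affine,
        dwi.gradients.subset(shell_idx),
        brain_mask=dwi.brain_mask,
    )
    b0s = DWIVolume(
        dwi.data[..., b0_idx],
        dwi.affine,
        dwi.gradients.subset(b0_idx),
        brain_mask=dwi.brain_mask,
    )
    return shell, b0s


def normalize_by_b0(
    shell: DWIVolume, b0s: DWIVolume, epsilon: float = 1e-6
) -> DWIVolume:
    """Divide each voxel's shell signal by its mean b0 signal.

    Voxels whose mean b0 is at or below ``epsilon`` are set to 0; their
    count is logged.
    """
    if shell.spatial_shape != b0s.spatial_shape:
        raise ShapeError("shell and b0 volumes have different spatial shapes")
    mean_b0 = b0s.data.mean(axis=3)
    if np.all(mean_b0 <= epsilon):
        raise DataError("b0 volume is zero everywhere; cannot normalize")
    bad = mean_b0 <= epsilon
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("normalize_by_b0: %d voxels with ~zero b0 set to 0", n_bad)
    safe = np.where(bad, 1.0, mean_b0)
    out = shell.data / safe[..., None]
    out[bad] = 0.0
    return DWIVolume(out, shell.affine, shell.gradients, brain_mask=shell.brain_mask)


def fit_sh(shell: DWIVolume, lmax: int = 4, cond_max: float = 1e8) -> SHVolume:
    """Project per-voxel shell signal onto real even-degree SH coefficients.

    Solves the least-squares system B c = s per voxel, with B the SH design
    matrix at the shell's gradient directions.
    """
    m = shbasis.n_coeffs(lmax)
    dirs = shell.gradients.directions
    g = dirs.shape[0]
    if g < m:
        raise ConditioningError(
            f"{g} directions cannot determine {m} SH coefficients (lmax={lmax})"
        )
    b = shbasis.design_matrix(dirs, lmax)
    cond = np.linalg.cond(b)
    if not np.isfinite(cond) or cond > cond_max:
        raise ConditioningError(
            f"SH design matrix is ill-conditioned (condition number {cond:.3g}); "
            "directions may be coplanar or duplicated"
        )
    solver = np.linalg.pinv(b)  # (M, G)
    coeffs = shell.data.reshape(-1, g) @ solver.T
    coeffs = coeffs.reshape(shell.spatial_shape + (m,))
    return SHVolume(coeffs, lmax, shell.affine)


def clamp_outliers(
    sh: SHVolume,
    low_pct: float = 5.0,
    high_pct: float = 99.0,
    mask: BrainMask | None = None,
) -> SHVolume:
    """Clamp each coefficient channel to its in-mask percentile interval.

    Percentiles use linear interpolation between order statistics and are
    computed per channel over in-mask voxels (channel scales differ by
    orders of magnitude, so a global clamp would only touch c00).
    """
    if not 0.0 <= low_pct < high_pct <= 100.0:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    flat = sh.coeffs.reshape(-1, sh.n_coeffs)
    if mask is not None:
        if mask.mask.shape != sh.spatial_shape:
            raise ShapeError("mask shape does not match SH volume")
        sel = mask.mask.reshape(-1)
        if not sel.any():
            raise DataError("empty brain mask")
        sample = flat[sel]
    else:
        sample = flat
    lo = np.percentile(sample, low_pct, axis=0)
    hi = np.percentile(sample, high_pct, axis=0)
    out = np.clip(flat, lo[None, :], hi[None, :]).reshape(sh.coeffs.shape)
    return SHVolume(out, sh.lmax, sh.affine, sh.basis)


def _pair_energy(d: np.ndarray, e: np.ndarray, eps: float = 1e-12) -> float:
    """Electrostatic repulsion between two directions with antipodal symmetry."""
    a = np.linalg.norm(d - e)
    b = np.linalg.norm(d + e)
    if min(a, b) < 1e-8:
        return np.inf
    return 1.0 / max(a, eps) + 1.0 / max(b, eps)


def reorder_gradients(gtab: GradientTable) -> tuple[GradientTable, np.ndarray]:
    """Reorder directions so every truncation prefix is well spread.

    Greedy electrostatic ordering on the half-sphere: starting from the
    first diffusion-weighted direction, repeatedly append the direction
    whose added pairwise repulsion energy (with antipodal symmetry) against
    the already-chosen prefix is smallest, ties broken by input index. b0
    frames are interleaved evenly among the reordered directions.

    Returns the reordered table and the permutation of original frame
    indices it realizes.
    """
    dw_idx = np.where(~gtab.b0_mask)[0]
    b0_idx = np.where(gtab.b0_mask)[0]
    if dw_idx.size < 2:
        raise SelectionError("need at least 2 diffusion-weighted directions")
    dirs = gtab.directions[dw_idx]
    n = dw_idx.size
    # pairwise energies once; inf marks antipodal duplicates
    energy = np.empty((n, n))
    for i in range(n):
        energy[i, i] = 0.0
        for j in range(i + 1, n):
            energy[i, j] = energy[j, i] = _pair_energy(dirs[i], dirs[j])
    if np.isinf(energy).any():
        warnings.warn(
            "duplicate (antipodally identical) gradient directions; "
            "ordering ties broken by input index",
            stacklevel=2,
        )
        finite_max = energy[np.isfinite(energy)].max(initial=1.0)
        energy = np.where(np.isinf(energy), 1e12 * max(finite_max, 1.0), energy)
    chosen = [0]
    remaining = list(range(1, n))
    while remaining:
        added = [energy[chosen, r].sum() for r in remaining]
        k = int(np.argmin(added))  # argmin takes the first minimum: index tie-break
        chosen.append(remaining.pop(k))
    ordered_dw = dw_idx[chosen]
    # interleave b0 frames evenly among the ordered directions
    perm: list[int] = []
    n_b0 = b0_idx.size
    if n_b0 == 0:
        perm = list(ordered_dw)
    else:
        spacing = (n + n_b0) / n_b0
        b0_positions = {int(np.floor(i * spacing)) for i in range(n_b0)}
        it_dw = iter(ordered_dw)
        it_b0 = iter(b0_idx)
        for pos in range(n + n_b0):
            if pos in b0_positions:
                perm.append(int(next(it_b0)))
            else:
                perm.append(int(next(it_dw)))
    perm_arr = np.asarray(perm, dtype=int)
    return gtab.subset(perm_arr), perm_arr


def prefix_energy(directions: np.ndarray, k: int) -> float:
    """Total antipodally symmetric repulsion energy of the first k directions."""
    e = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            e += _pair_energy(directions[i], directions[j])
    return e


def truncate_gradients(dwi: DWIVolume, n_directions: int = 45) -> DWIVolume:
    """Keep the first ``n_directions`` diffusion-weighted frames.

    Emulates a shorter clinical acquisition: after :func:`reorder_gradients`
    the retained prefix stays close to optimally spread. A proportional
    number of leading b0 frames is kept, and frame order is preserved.
    """
    dw_idx = np.where(~dwi.gradients.b0_mask)[0]
    b0_idx = np.where(dwi.gradients.b0_mask)[0]
    if n_directions <= 0:
        raise SelectionError("n_directions must be positive (no shell would remain)")
    if n_directions > dw_idx.size:
        raise SelectionError(
            f"requested {n_directions} directions but only {dw_idx.size} available"
        )
    n_b0_keep = max(1, int(round(b0_idx.size * n_directions / dw_idx.size)))
    n_b0_keep = min(n_b0_keep, b0_idx.size) if b0_idx.size else 0
    keep = np.sort(
        np.concatenate([dw_idx[:n_directions], b0_idx[:n_b0_keep]]).astype(int)
    )
    return DWIVolume(
        dwi.data[..., keep],
        dwi.affine,
        dwi.gradients.subset(keep),
        brain_mask=dwi.brain_mask,
    )


def preprocess_dwi(
    dwi: DWIVolume,
    b_target: float = 2000.0,
    tolerance: float = 100.0,
    lmax: int = 4,
    low_pct: float = 5.0,
    high_pct: float = 99.0,
) -> SHVolume:
    """Full preprocessing chain: shell -> b0 normalize -> SH fit -> clamp.

    When the DWI carries a brain mask, percentile clamping is computed over
    in-mask voxels and the background is zeroed afterwards.
    """
    shell, b0s = extract_shell(dwi, b_target, tolerance)
    norm = normalize_by_b0(shell, b0s)
    sh = fit_sh(norm, lmax)
    if dwi.brain_mask is not None:
        mask = BrainMask(dwi.brain_mask, dwi.affine)
        sh = clamp_outliers(sh, low_pct, high_pct, mask)
        sh.coeffs[~mask.mask] = 0.0
    else:
        sh = clamp_outliers(sh, low_pct, high_pct, None)
    return sh


def save_sh(sh: SHVolume, path) -> None:
    """Write an SH volume as a 4D NIfTI (basis recorded in the header descrip)."""
    img = nib.Nifti1Image(sh.coeffs.astype(np.float32), sh.affine)
    img.header["descrip"] = f"SH lmax={sh.lmax} basis={sh.basis}".encode()[:79]
    nib.save(img, str(path))
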