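"""Real even-degree spherical-harmonic basis.

dMRI signal on a shell is antipodally symmetric, so only even degrees carry
signal; the basis keeps degrees l = 0, 2, ..., lmax with orders m = -l..l,
in that "descriptive" ordering. Functions are orthonormal on the unit
sphere: for m < 0 the basis function is sqrt(2) * Im(Y_l^{|m|}), for m = 0
it is Y_l^0, and for m > 0 it is sqrt(2) * Re(Y_l^m), with Y_l^m the
complex spherical harmonic of scipy (Condon-Shortley phase included).
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

from .errors import ShapeError


def n_coeffs(lmax: int) -> int:
    """Number of even-degree real SH functions up to lmax: (lmax+1)(lmax+2)/2."""
    if lmax % 2 != 0 or lmax < 0:
        raise ShapeError("lmax must be even and non-negative")
    return (lmax + 1) * (lmax + 2) // 2


def sh_index_list(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs in storage order: l = 0, 2, ..., lmax; m = -l..l."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def degree_slices(lmax: int) -> dict[int, slice]:
    """Map each even degree l to its contiguous slice of coefficient channels."""
    out, start = {}, 0
    for l in range(0, lmax + 1, 2):
        out[l] = slice(start, start + 2 * l + 1)
        start += 2 * l + 1
    return out


def design_matrix(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real even-degree SH basis at unit directions.

    Parameters
    ----------
    directions : (G, 3) array of unit vectors.
    lmax : maximum (even) SH degree.

    Returns
    -------
    (G, M) matrix B with B[g, i] = Y_i(direction g), M = n_coeffs(lmax).
    """
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ShapeError(f"directions must be (G, 3), got {d.shape}")
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth
    cols = []
    for l, m in sh_index_list(lmax):
        ylm = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * ylm.imag)
        elif m == 0:
            cols.append(ylm.real)
        else:
            cols.append(np.sqrt(2.0) * ylm.real)
    return np.stack(cols, axis=1)


def synthesize(coeffs: np.ndarray, directions: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the SH expansion with the given coefficients at directions.

    `coeffs` may be a single M-vector or an (..., M) stack; the result has
    shape (..., G).
    """
    b = design_matrix(directions, lmax)
    c = np.asarray(coeffs, dtype=float)
    if c.shape[-1] != b.shape[1]:
        raise ShapeError(
            f"coefficient length {c.shape[-1]} does not match lmax={lmax} "
            f"(expected {b.shape[1]})"
        )
    return c @ b.T
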