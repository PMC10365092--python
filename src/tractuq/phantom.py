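"""Synthetic tract phantoms: tube-shaped "tracts" with a consistent
single-shell DWI signal, so every pipeline stage runs without any
external data.

Each tract is the set of voxels within a radius of a smooth curve —
straight, C-shaped, or S-shaped templates echoing the gross geometry of
real bundles (e.g. corticospinal tract vs. arcuate-like curves). The
curve tangent defines a per-voxel principal fiber direction. The DWI
signal follows an axially symmetric single-tensor model,

    S(g) = S0 * exp(-b * [l_perp + (l_par - l_perp) * (g . d)^2])

inside tracts, isotropic attenuation elsewhere in the "brain" (an
ellipsoidal mask), plus Gaussian or Rician noise. Diffusivities are in
mm^2/s; with the defaults (l_par = 1.7e-3, ratio 5, b = 2000 s/mm^2) the
degree-2 SH energy of tract voxels sits well above the noise floor, which
is what makes desk-scale training of the segmentation network feasible.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .core import BrainMask, DWIVolume, GradientTable, TractMaskSet
from .errors import ConfigurationError
from .rotation import fibonacci_sphere


@dataclass
class PhantomSpec:
    """Geometry, signal, and acquisition parameters of a phantom subject."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 1.0
    n_tracts: int = 3
    tube_radius: float = 2.5  # voxels
    curve_amplitude: float = 5.0  # voxels, bending of C/S templates
    jitter: float = 1.5  # voxels, subject-to-subject control-point jitter
    s0: float = 100.0
    b_value: float = 2000.0  # s/mm^2
    lambda_parallel: float = 1.7e-3  # mm^2/s
    anisotropy_ratio: float = 5.0  # lambda_parallel / lambda_perp
    lambda_iso: float = 0.9e-3  # background (gray-matter-like) diffusivity
    noise_sd: float = 2.0  # same units as s0
    noise_model: str = "rician"
    n_directions: int = 60
    n_b0: int = 6

    def __post_init__(self) -> None:
        if self.tube_radius < 1.0:
            raise ConfigurationError("tube radius must be >= 1 voxel")
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError("noise_model must be 'gaussian' or 'rician'")
        if self.n_tracts < 1 or self.n_tracts > 3:
            raise ConfigurationError("supported n_tracts: 1..3 template curves")

    @property
    def lambda_perp(self) -> float:
        return self.lambda_parallel / self.anisotropy_ratio

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a


@dataclass
class PhantomSubject:
    """One synthetic subject, mirroring the real-data layout."""

    dwi: DWIVolume
    brain: BrainMask
    tracts: TractMaskSet
    directions: np.ndarray  # (X, Y, Z, 3) unit fiber direction inside tracts
    subject_id: str = ""
    spec: PhantomSpec = field(default_factory=PhantomSpec)


def _template_curve(
    kind: str, shape, amplitude: float, offsets: np.ndarray, n_pts: int = 200
) -> np.ndarray:
    """Points of a smooth curve crossing the grid along x.

    kind: 'straight', 'c', or 's'; offsets shift the curve's y/z anchor and
    scale its amplitude (subject jitter).
    """
    sx, sy, sz = shape
    margin = 4.0
    t = np.linspace(0.0, 1.0, n_pts)
    x = margin + (sx - 1 - 2 * margin) * t
    y0, z0, amp_j = offsets
    amp = amplitude + amp_j
    # curves stay well inside the ellipsoidal brain mask so the tube
    # cross-section is never clipped (placement echoes deep white matter)
    if kind == "straight":
        y = np.full_like(t, sy * 0.50 + y0)
        z = np.full_like(t, sz * 0.34 + z0)
    elif kind == "c":
        y = sy * 0.36 + y0 + amp * np.sin(np.pi * t)
        z = np.full_like(t, sz * 0.54 + z0)
    elif kind == "s":
        # bends in x-z, unlike the C template's x-y plane: distinct tract
        # classes carry distinct local orientation signatures, as real
        # bundles do (e.g. inferior-superior CST vs anterior-posterior ILF)
        y = np.full_like(t, sy * 0.62 + y0)
        z = sz * 0.62 + z0 + amp * 0.7 * np.sin(2 * np.pi * t)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown curve template {kind!r}")
    return np.stack([x, y, z], axis=1)


_TEMPLATES = ("straight", "c", "s")


def brain_mask_for(spec: PhantomSpec) -> BrainMask:
    """Ellipsoid inscribed in the grid (with a small margin)."""
    shape = np.asarray(spec.shape, dtype=float)
    center = (shape - 1) / 2.0
    radii = shape / 2.0 - 1.0
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij"), -1)
    d = ((idx - center) / radii) ** 2
    return BrainMask(d.sum(axis=-1) <= 1.0, spec.affine)


def make_tract_masks(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[TractMaskSet, np.ndarray]:
    """Voxelize the template curves into tube masks plus a direction field.

    A voxel belongs to a tract when its center lies within ``tube_radius``
    of the (densely sampled) curve; its fiber direction is the tangent at
    the nearest curve point of the nearest tract. Overlaps between tracts
    are allowed (multi-label), the direction following the closest curve.
    """
    shape = spec.shape
    brain = brain_mask_for(spec)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1
    ).reshape(-1, 3).astype(float)
    masks = np.zeros(shape + (spec.n_tracts,), dtype=bool)
    dirs = np.zeros(shape + (3,))
    best = np.full(np.prod(shape), np.inf)
    for n in range(spec.n_tracts):
        offsets = rng.uniform(-spec.jitter, spec.jitter, size=3)
        pts = _template_curve(_TEMPLATES[n], shape, spec.curve_amplitude, offsets)
        if np.any(pts < -0.5) or np.any(pts > np.asarray(shape) - 0.5):
            raise ConfigurationError("curve leaves the grid; reduce amplitude/jitter")
        tangents = np.gradient(pts, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        tree = cKDTree(pts)
        dist, nearest = tree.query(idx)
        inside = dist <= spec.tube_radius
        masks[..., n] = inside.reshape(shape)
        closer = inside & (dist < best)
        dirs.reshape(-1, 3)[closer] = tangents[nearest[closer]]
        best = np.where(closer, dist, best)
    masks &= brain.mask[..., None]
    return TractMaskSet(masks, spec.affine), dirs


def gradient_scheme(spec: PhantomSpec) -> GradientTable:
    """b0 frames followed by well-spread single-shell directions."""
    dirs = np.concatenate(
        [np.zeros((spec.n_b0, 3)), fibonacci_sphere(spec.n_directions)]
    )
    bvals = np.concatenate(
        [np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)]
    )
    return GradientTable(dirs, bvals)


def make_dwi(
    masks: TractMaskSet,
    directions: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> DWIVolume:
    """Synthesize the single-shell DWI signal consistent with the masks."""
    gtab = gradient_scheme(spec)
    brain = brain_mask_for(spec)
    shape = spec.shape
    in_tract = masks.data.any(axis=3)
    signal = np.zeros(shape + (gtab.n,))
    b0_frames = gtab.b0_mask
    # b0: S0 inside the brain
    signal[..., b0_frames] = spec.s0 * brain.mask[..., None]
    g = gtab.directions[~b0_frames]  # (Gd, 3)
    # isotropic background
    iso = spec.s0 * np.exp(-spec.b_value * spec.lambda_iso)
    bg = brain.mask & ~in_tract
    dw = np.zeros(shape + (g.shape[0],))
    dw[bg] = iso
    # anisotropic tract signal
    d = directions[in_tract]  # (V, 3)
    cos2 = (d @ g.T) ** 2
    adc = spec.lambda_perp + (spec.lambda_parallel - spec.lambda_perp) * cos2
    dw[in_tract] = spec.s0 * np.exp(-spec.b_value * adc)
    signal[..., ~b0_frames] = dw
    # noise
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
            signal = np.maximum(signal, 0.0)
        else:  # rician: magnitude of complex Gaussian around the signal
            re = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
            im = rng.normal(0.0, spec.noise_sd, size=signal.shape)
            signal = np.hypot(re, im)
    return DWIVolume(signal, spec.affine, gtab, brain_mask=brain.mask)


def make_subject(
    spec: PhantomSpec, seed: int | np.random.SeedSequence, subject_id: str = ""
) -> PhantomSubject:
    rng = np.random.default_rng(seed)
    tracts, dirs = make_tract_masks(spec, rng)
    dwi = make_dwi(tracts, dirs, spec, rng)
    return PhantomSubject(
        dwi=dwi,
        brain=BrainMask(dwi.brain_mask, spec.affine),
        tracts=tracts,
        directions=dirs,
        subject_id=subject_id,
        spec=spec,
    )


def make_dataset(
    n_subjects: int, spec: PhantomSpec | None = None, seed: int = 0
) -> list[PhantomSubject]:
    """Generate n reproducible subjects with geometric jitter between them."""
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if spec is None:
        spec = PhantomSpec()
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        make_subject(spec, streams[i], subject_id=f"phantom-{i:03d}")
        for i in range(n_subjects)
    ]


def noise_sweep(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    sd_range: tuple[float, float] = (0.5, 12.0),
) -> list[PhantomSubject]:
    """Subjects with linearly increasing noise SD (uncertainty ensembles)."""
    if spec is None:
        spec = PhantomSpec()
    sds = np.linspace(sd_range[0], sd_range[1], n_subjects)
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        make_subject(
            replace(spec, noise_sd=float(sds[i])),
            streams[i],
            subject_id=f"phantom-noise-{i:03d}",
        )
        for i in range(n_subjects)
    ]
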