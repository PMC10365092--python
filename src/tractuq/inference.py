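"""Whole-volume prediction and stochastic inference.

Three stochastic modes produce a stack of T probability volumes per
subject:

* TTD (test-time dropout): encoder dropout stays active at inference,
  sampling approximate posterior weights — epistemic uncertainty.
* TTA (test-time augmentation): each pass rotates the input (grid + SH
  coefficients jointly), predicts, and maps the probabilities back to
  subject space with the inverse spatial rotation — aleatoric uncertainty.
* Hybrid: both per pass.

The voxelwise mean over passes is the final prediction; the voxelwise SD
is the uncertainty map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import SHVolume, TractMaskSet
from .errors import ConfigurationError, ShapeError
from .rotation import (
    RotationSpec,
    resample_rotated,
    rotate_volume_and_sh,
    sample_rotation,
)
from .unet import UNet3D

MODES = ("deterministic", "ttd", "tta", "hybrid")


@dataclass
class InferenceConfig:
    """Stochastic inference settings (T=20 passes, r from the model)."""

    mode: str = "hybrid"
    passes: int = 20
    augmentation_range_deg: float = 20.0
    window_size: int = 64
    overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        if self.passes < 1:
            raise ConfigurationError("passes must be >= 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ConfigurationError("overlap must be in [0, 1)")


@dataclass
class ProbabilityStack:
    """T stochastic probability volumes for one subject, in subject space."""

    probs: np.ndarray  # (T, X, Y, Z, N) in [0, 1]
    mode: str
    subject_id: str = ""
    transforms: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.probs.ndim != 5:
            raise ShapeError("stack must be (T, X, Y, Z, N)")

    @property
    def n_passes(self) -> int:
        return self.probs.shape[0]

    @property
    def n_tracts(self) -> int:
        return self.probs.shape[4]


@dataclass
class UncertaintyResult:
    """Mean prediction and voxelwise SD uncertainty map."""

    mean_prob: np.ndarray  # (X, Y, Z, N)
    sd_map: np.ndarray  # (X, Y, Z, N), >= 0


def _window_starts(dim: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, max(dim - window, 0) + 1, stride))
    last = dim - window
    if starts[-1] != last and last > 0:
        starts.append(last)
    return starts


def predict_volume(
    model: UNet3D,
    sh: SHVolume,
    cfg: InferenceConfig,
    dropout_active: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sliding-window whole-volume prediction with uniform overlap averaging.

    Windows of cfg.window_size (clipped to the padded volume and rounded to
    the network's divisibility constraint) cover the grid with the
    configured overlap; overlapping predictions are averaged with equal
    weights. Returns an (X, Y, Z, N) probability volume.
    """
    data = sh.coeffs
    shape = np.asarray(data.shape[:3])
    step = 2 ** model.config.depth
    window = min(cfg.window_size, int(shape.min()))
    window = max(step, (window // step) * step)
    pad = np.maximum(window - shape, 0)
    if np.any(pad > 0):
        data = np.pad(data, [(0, int(p)) for p in pad] + [(0, 0)])
        shape = np.asarray(data.shape[:3])
    stride = max(1, int(round(window * (1.0 - cfg.overlap))))
    acc = np.zeros(tuple(shape) + (model.config.out_channels,))
    cnt = np.zeros(tuple(shape) + (1,))
    for sx in _window_starts(int(shape[0]), window, stride):
        for sy in _window_starts(int(shape[1]), window, stride):
            for sz in _window_starts(int(shape[2]), window, stride):
                sl = (
                    slice(sx, sx + window),
                    slice(sy, sy + window),
                    slice(sz, sz + window),
                )
                probs = model.forward(data[sl], dropout_active=dropout_active, rng=rng)
                acc[sl] += probs
                cnt[sl] += 1.0
    out = acc / cnt
    orig = sh.coeffs.shape[:3]
    return out[: orig[0], : orig[1], : orig[2]]


def _inverse(rot: RotationSpec) -> RotationSpec:
    angles = Rotation.from_matrix(rot.matrix.T).as_euler("xyz", degrees=True)
    return RotationSpec(tuple(angles.tolist()))


def run_stochastic(
    model: UNet3D, sh: SHVolume, cfg: InferenceConfig
) -> ProbabilityStack:
    """Draw T stochastic probability volumes (TTD, TTA, or Hybrid).

    Each pass owns an independent RNG stream spawned from cfg.seed, so
    results are reproducible and the first T passes of a longer run equal a
    shorter run's passes. TTA passes are mapped back to subject space with
    the inverse spatial rotation before stacking.
    """
    if cfg.mode == "deterministic":
        raise ConfigurationError(
            "mode='deterministic' draws no stochastic passes; use predict_volume"
        )
    use_dropout = cfg.mode in ("ttd", "hybrid")
    use_aug = cfg.mode in ("tta", "hybrid")
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.passes)
    stack = []
    transforms = []
    for t in range(cfg.passes):
        rng = np.random.default_rng(streams[t])
        record: dict = {"pass": t, "dropout": use_dropout}
        if use_aug:
            rot = sample_rotation(cfg.augmentation_range_deg, rng)
            record["angles_deg"] = list(rot.angles)
            sh_t, _ = rotate_volume_and_sh(sh, None, rot)
            probs = predict_volume(
                model, sh_t, cfg, dropout_active=use_dropout, rng=rng
            )
            probs = resample_rotated(probs, sh.affine, _inverse(rot), order=1)
            probs = np.clip(probs, 0.0, 1.0)
        else:
            probs = predict_volume(
                model, sh, cfg, dropout_active=use_dropout, rng=rng
            )
        stack.append(probs)
        transforms.append(record)
    return ProbabilityStack(
        probs=np.stack(stack, axis=0), mode=cfg.mode, transforms=transforms
    )


def summarize(stack: ProbabilityStack) -> UncertaintyResult:
    """Voxelwise mean and population SD (divisor T) over the T passes.

    Voxels where all passes agree exactly get SD exactly 0 (fp round-off
    from the mean subtraction is suppressed)."""
    mean = stack.probs.mean(axis=0)
    sd = stack.probs.std(axis=0)  # numpy default ddof=0: population SD
    agree = stack.probs.max(axis=0) == stack.probs.min(axis=0)
    sd[agree] = 0.0
    return UncertaintyResult(mean_prob=mean, sd_map=sd)


def binarize(
    probs: np.ndarray, threshold: float = 0.5, affine: np.ndarray | None = None
) -> TractMaskSet:
    """Threshold probabilities at >= threshold (inclusive) into tract masks."""
    p = np.asarray(probs)
    if p.ndim == 3:
        p = p[..., None]
    if p.ndim != 4:
        raise ShapeError("probability volume must be (X, Y, Z[, N])")
    return TractMaskSet(
        p >= threshold, affine if affine is not None else np.eye(4)
    )
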