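"""Training: class weighting, weighted binary cross-entropy, masked patch
sampling, step-halving learning schedule, and the SGD training loop.

One optimizer step is taken per subject visit, averaging gradients over
that visit's patch batch; every visit draws a fresh random rotation
(applied jointly to grid and SH coefficients) and a fresh set of patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import BrainMask, SHVolume, TractMaskSet
from .errors import ConfigurationError, DataError, ShapeError, TractUQError
from .rotation import rotate_volume_and_sh, sample_rotation
from .unet import UNet3D

logger = logging.getLogger(__name__)

_EPS = 1e-7  # probability clipping keeping the cross-entropy finite


@dataclass
class ClassWeights:
    """Inverse-frequency class weights w_n = max(C) / c_n."""

    counts: np.ndarray  # per-class positive-voxel totals over the training set
    weights: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class PatchBatch:
    """A batch of co-registered input/target patches with their origins."""

    inputs: np.ndarray  # (B, S, S, S, M)
    targets: np.ndarray  # (B, S, S, S, N)
    centers: np.ndarray  # (B, 3) voxel indices of patch centers


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Full-scale defaults: 400 epochs, learning rate 1e-3 halved every 50
    epochs, weight decay 1e-6, 50 patches of 64^3 per subject visit,
    rotation augmentation of +-20 degrees per axis. The optimizer family is
    SGD with momentum 0.9 (only rate and decay are externally pinned).
    """

    epochs: int = 400
    initial_lr: float = 1e-3
    lr_halving_period: int = 50
    weight_decay: float = 1e-6
    momentum: float = 0.9
    patch_size: int = 64
    patches_per_subject: int = 50
    augmentation_range_deg: float = 20.0
    seed: int = 0
    voxel_mean_loss: bool = True  # scale-stable 1/J normalization in the loop
    batch_size: int | None = None  # patches per optimizer step; None = whole visit


@dataclass
class Subject:
    """One training subject: SH image, multi-label tract masks, brain mask."""

    sh: SHVolume
    tracts: TractMaskSet
    brain: BrainMask
    subject_id: str = ""


def prepare_subjects(phantoms, lmax: int = 4, **preprocess_kw) -> list[Subject]:
    """Preprocess phantom subjects into training-ready SH subjects."""
    from .preprocess import preprocess_dwi

    out = []
    for ph in phantoms:
        sh = preprocess_dwi(
            ph.dwi, b_target=ph.spec.b_value, lmax=lmax, **preprocess_kw
        )
        out.append(
            Subject(sh=sh, tracts=ph.tracts, brain=ph.brain, subject_id=ph.subject_id)
        )
    return out


def compute_class_weights(mask_sets: list[TractMaskSet]) -> ClassWeights:
    """Sum positive voxels per class over subjects; weights = max(C)/c_n.

    The largest class gets weight 1 and rarer classes proportionally more,
    so small tracts are not drowned out by background-dominated classes.
    """
    if not mask_sets:
        raise ConfigurationError("need at least one subject")
    counts = np.zeros(mask_sets[0].n_tracts, dtype=float)
    for ms in mask_sets:
        if ms.n_tracts != counts.shape[0]:
            raise ShapeError("subjects disagree on number of tract classes")
        counts += ms.data.reshape(-1, ms.n_tracts).sum(axis=0)
    if np.any(counts == 0):
        empty = np.where(counts == 0)[0].tolist()
        raise ConfigurationError(
            f"classes {empty} have no positive voxels in the training set"
        )
    weights = counts.max() / counts
    return ClassWeights(counts=counts, weights=weights)


def wbce_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    voxel_mean: bool = False,
) -> float:
    """Class-weighted binary cross-entropy.

    ``-(1/N) sum_n w_n sum_j [y log p + (1-y) log(1-p)]`` with predictions
    clipped to [1e-7, 1-1e-7]. ``voxel_mean`` additionally divides by the
    voxel count J, decoupling the loss scale from patch size.
    """
    p, y, w = _check_loss_args(pred, target, weights)
    j = p.shape[0]
    per_class = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum(axis=0)
    loss = float((w * per_class).sum() / w.shape[0])
    if voxel_mean:
        loss /= j
    return loss


def wbce_grad(
    pred: np.ndarray,
    target: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    voxel_mean: bool = False,
) -> np.ndarray:
    """Gradient of :func:`wbce_loss` w.r.t. the predictions, same shape."""
    p, y, w = _check_loss_args(pred, target, weights)
    g = -(y / p - (1.0 - y) / (1.0 - p)) * w[None, :] / w.shape[0]
    if voxel_mean:
        g /= p.shape[0]
    return g.reshape(np.asarray(pred).shape)


def _check_loss_args(pred, target, weights):
    p = np.asarray(pred, dtype=float)
    y = np.asarray(target, dtype=float)
    if p.shape != y.shape:
        raise ShapeError(f"pred {p.shape} vs target {y.shape}")
    if p.ndim == 1:
        p, y = p[:, None], y[:, None]
    n = p.shape[-1]
    p = np.clip(p.reshape(-1, n), _EPS, 1.0 - _EPS)
    y = y.reshape(-1, n)
    if weights is None:
        w = np.ones(n)
    elif isinstance(weights, ClassWeights):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ShapeError(f"{w.shape[0] if w.ndim else 1} weights for {n} classes")
    return p, y, w


def sample_patches(
    sh: SHVolume,
    masks: TractMaskSet,
    brain: BrainMask,
    n: int,
    size: int,
    rng: np.random.Generator,
) -> PatchBatch:
    """Sample n patches whose centers are uniform draws from in-mask voxels.

    Patches near the border are zero-padded to the full patch size.
    """
    if masks.spatial_shape != sh.spatial_shape or brain.mask.shape != sh.spatial_shape:
        raise ShapeError("sh/masks/brain grids disagree")
    in_mask = np.argwhere(brain.mask)
    if in_mask.shape[0] == 0:
        raise DataError("empty brain mask")
    m, nt = sh.n_coeffs, masks.n_tracts
    inputs = np.zeros((n, size, size, size, m))
    targets = np.zeros((n, size, size, size, nt))
    centers = in_mask[rng.integers(0, in_mask.shape[0], size=n)]
    half = size // 2
    shape = np.asarray(sh.spatial_shape)
    for b, c in enumerate(centers):
        lo = c - half
        hi = lo + size
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, shape)
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        ssl = tuple(slice(a, b_) for a, b_ in zip(src_lo, src_hi))
        dsl = tuple(slice(a, b_) for a, b_ in zip(dst_lo, dst_hi))
        inputs[b][dsl] = sh.coeffs[ssl]
        targets[b][dsl] = masks.data[ssl]
    return PatchBatch(inputs=inputs, targets=targets, centers=centers)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: initial_lr * 0.5 ** floor(epoch / halving period)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_period)


@dataclass
class TrainResult:
    model: UNet3D
    epoch_loss: list[float] = field(default_factory=list)
    class_weights: ClassWeights | None = None


def split_validation(
    subjects: list[Subject], fraction: float = 0.1, seed: int = 0
) -> tuple[list[Subject], list[Subject]]:
    """Seeded subject-level split; at least one validation subject if
    fraction > 0 and more than one subject is available."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_val = int(round(fraction * len(subjects)))
    if fraction > 0 and n_val == 0 and len(subjects) > 1:
        n_val = 1
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(subjects) if i not in val_idx]
    val = [s for i, s in enumerate(subjects) if i in val_idx]
    return train, val


def train(
    model: UNet3D, subjects: list[Subject], cfg: TrainConfig
) -> TrainResult:
    """Optimize the network on SH images with on-the-fly SH-aware rotation.

    Per epoch every subject is visited exactly once in random order; each
    visit rotates the subject (grid + coefficients + masks jointly), samples
    a fresh patch batch from within the rotated brain mask, and takes one
    SGD-with-momentum step on the batch-averaged weighted BCE gradient.
    Fully reproducible given cfg.seed.
    """
    if not subjects:
        raise ConfigurationError("need at least one training subject")
    weights = compute_class_weights([s.tracts for s in subjects])
    result = TrainResult(model=model, class_weights=weights)
    if cfg.epochs == 0:
        return result
    rng = np.random.default_rng(cfg.seed)
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        order = rng.permutation(len(subjects))
        epoch_losses = []
        for si in order:
            s = subjects[si]
            rot = sample_rotation(cfg.augmentation_range_deg, rng)
            joint = np.concatenate(
                [s.tracts.data, s.brain.mask[..., None]], axis=3
            )
            sh_aug, joint_aug = rotate_volume_and_sh(s.sh, joint, rot)
            tracts_aug = TractMaskSet(joint_aug[..., :-1], s.tracts.affine)
            brain_aug = BrainMask(joint_aug[..., -1], s.brain.affine)
            if not brain_aug.mask.any():  # rotation pushed mask out of view
                brain_aug = s.brain
                tracts_aug, sh_aug = s.tracts, s.sh
            batch = sample_patches(
                sh_aug, tracts_aug, brain_aug,
                cfg.patches_per_subject, cfg.patch_size, rng,
            )
            n_patches = batch.inputs.shape[0]
            step = cfg.batch_size or n_patches
            visit_loss = 0.0
            for start in range(0, n_patches, step):
                model.zero_grad()
                nb = min(step, n_patches - start)
                for b in range(start, start + nb):
                    probs = model.forward(
                        batch.inputs[b], dropout_active=True, rng=rng
                    )
                    visit_loss += wbce_loss(
                        probs, batch.targets[b], weights,
                        voxel_mean=cfg.voxel_mean_loss,
                    )
                    model.backward(
                        wbce_grad(
                            probs, batch.targets[b], weights,
                            voxel_mean=cfg.voxel_mean_loss,
                        )
                    )
                for p in model.params:
                    g = p.grad / nb + cfg.weight_decay * p.value
                    p.vel = cfg.momentum * p.vel - lr * g
                    p.value += p.vel
            visit_loss /= n_patches
            if not np.isfinite(visit_loss):
                raise TractUQError(
                    f"non-finite loss at epoch {epoch}, subject index {si}, lr {lr}"
                )
            epoch_losses.append(visit_loss)
        mean_loss = float(np.mean(epoch_losses))
        result.epoch_loss.append(mean_loss)
        logger.info("epoch %d: lr=%.2e loss=%.5f", epoch, lr, mean_loss)
    return result
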