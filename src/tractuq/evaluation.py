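"""Segmentation metrics, structure-wise uncertainty, and residual maps.

Overlap metrics (Dice, sensitivity, specificity) come from voxelwise
confusion counts; surface metrics (Hausdorff, ASSD) from Euclidean
distances between mask boundaries in millimeters. Structure-wise
uncertainty is summarized by the volume variation coefficient (VVC), the
coefficient of variation of per-pass binary segmentation volumes, and its
association with segmentation error is quantified by Spearman rank
correlation.

Two sensitivity/specificity conventions are provided. "standard" is the
usual tp/(tp+fn) and tn/(tn+fp); "as_printed" follows a common alternative
wording (true positives over all predicted positives, i.e. precision, and
the analogous negative-side ratio) so reports can state exactly which was
used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import TractMaskSet
from .errors import ShapeError
from .inference import ProbabilityStack

CONVENTIONS = ("standard", "as_printed")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SurfaceDistanceSet:
    """Directed boundary distances (mm), predicted->truth and truth->predicted."""

    pred_to_truth: np.ndarray
    truth_to_pred: np.ndarray

    @property
    def union(self) -> np.ndarray:
        return np.concatenate([self.pred_to_truth, self.truth_to_pred])


@dataclass
class VolumeSeries:
    """Per-pass binary segmentation volumes with mean and population SD."""

    volumes: np.ndarray
    mean: float
    sd: float


def confusion(
    pred: np.ndarray, truth: np.ndarray, eval_mask: np.ndarray | None = None
) -> ConfusionCounts:
    """Voxelwise confusion counts, optionally restricted to eval_mask."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ShapeError(f"pred {p.shape} vs truth {t.shape}")
    if eval_mask is not None:
        m = np.asarray(eval_mask).astype(bool)
        if m.shape != p.shape:
            raise ShapeError("eval_mask shape mismatch")
        p, t = p[m], t[m]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice(counts: ConfusionCounts) -> float:
    """2*tp / (2*tp + fp + fn); 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def sensitivity(counts: ConfusionCounts, convention: str = "standard") -> float:
    """tp/(tp+fn) ("standard") or tp/(tp+fp) ("as_printed"); NaN if undefined."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    denom = counts.tp + (counts.fn if convention == "standard" else counts.fp)
    return counts.tp / denom if denom else float("nan")


def specificity(counts: ConfusionCounts, convention: str = "standard") -> float:
    """tn/(tn+fp) ("standard") or tn/(tn+fn) ("as_printed"); NaN if undefined."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    denom = counts.tn + (counts.fp if convention == "standard" else counts.fn)
    return counts.tn / denom if denom else float("nan")


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background face-neighbor
    (the grid edge counts as background)."""
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE, border_value=0)
    return mask & ~eroded


def surface_distances(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SurfaceDistanceSet:
    """Euclidean nearest-boundary distances in mm, in both directions."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ShapeError(f"pred {p.shape} vs truth {t.shape}")
    if not p.any() or not t.any():
        raise ValueError("surface distances are undefined for an empty mask")
    bp, bt = _boundary(p), _boundary(t)
    dist_to_t = ndimage.distance_transform_edt(~bt, sampling=spacing)
    dist_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing)
    return SurfaceDistanceSet(
        pred_to_truth=dist_to_t[bp], truth_to_pred=dist_to_p[bt]
    )


def hausdorff(sd: SurfaceDistanceSet) -> float:
    """Maximum over both directed boundary-distance sets (mm)."""
    return float(sd.union.max())


def assd(sd: SurfaceDistanceSet) -> float:
    """Average over both directed boundary-distance sets (mm)."""
    return float(sd.union.mean())


def _pass_masks(stack: ProbabilityStack, tract: int, threshold: float) -> np.ndarray:
    return stack.probs[..., tract] >= threshold


def vvc(
    stack: ProbabilityStack | np.ndarray,
    threshold: float = 0.5,
    tract: int = 0,
) -> tuple[VolumeSeries, float]:
    """Volume variation coefficient: sigma/mu of per-pass binary volumes.

    Each of the T passes is thresholded (inclusive) and its foreground
    voxels counted; VVC is the population SD over the mean of those counts.
    Returns (VolumeSeries, vvc); vvc is NaN when the mean volume is zero.
    """
    if isinstance(stack, ProbabilityStack):
        masks = _pass_masks(stack, tract, threshold)
    else:
        masks = np.asarray(stack) >= threshold
    t = masks.shape[0]
    if t < 2:
        raise ValueError("VVC needs at least 2 passes")
    v = masks.reshape(t, -1).sum(axis=1).astype(float)
    mu = float(v.mean())
    sigma = float(v.std())  # population SD
    series = VolumeSeries(volumes=v, mean=mu, sd=sigma)
    return series, (sigma / mu if mu > 0 else float("nan"))


def mean_pass_dice(
    stack: ProbabilityStack | np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    tract: int = 0,
) -> float:
    """Average of per-pass Dice scores against the ground truth."""
    if isinstance(stack, ProbabilityStack):
        masks = _pass_masks(stack, tract, threshold)
    else:
        masks = np.asarray(stack) >= threshold
    t_arr = np.asarray(truth).astype(bool)
    scores = [dice(confusion(masks[i], t_arr)) for i in range(masks.shape[0])]
    return float(np.mean(scores))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN when a
    variable has zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    if np.unique(x).size == x.size and np.unique(y).size == y.size:
        # tie-free: the classical rank-difference formula is exact, so a
        # perfect monotone relation yields exactly +-1
        n = x.size
        d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
        return float(1.0 - 6.0 * np.sum(d.astype(float) ** 2) / (n * (n**2 - 1)))
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def residual_map(truth: TractMaskSet | np.ndarray, mean_prob: np.ndarray) -> np.ndarray:
    """Signed residuals y - y_hat in [-1, 1], voxel by voxel."""
    t = truth.data if isinstance(truth, TractMaskSet) else np.asarray(truth)
    p = np.asarray(mean_prob)
    if t.shape != p.shape:
        raise ShapeError(f"truth {t.shape} vs probabilities {p.shape}")
    return t.astype(float) - p


def evaluate_subject(
    stack: ProbabilityStack,
    truth: TractMaskSet,
    threshold: float = 0.5,
    convention: str = "standard",
    subject_id: str = "",
) -> pd.DataFrame:
    """Per-tract metric report for one subject (one row per tract).

    Overlap metrics are computed on the thresholded mean probability;
    surface metrics are in mm via the mask affine; VVC and mean-pass Dice
    summarize the stochastic stack.
    """
    from .inference import summarize

    mean_prob = summarize(stack).mean_prob
    spacing = tuple(np.abs(np.diag(truth.affine[:3, :3])).tolist())
    rows = []
    for n in range(truth.n_tracts):
        pred = mean_prob[..., n] >= threshold
        gt = truth.data[..., n]
        c = confusion(pred, gt)
        row = {
            "subject": subject_id,
            "tract": n,
            "dice": dice(c),
            "sensitivity": sensitivity(c, convention),
            "specificity": specificity(c, convention),
            "convention": convention,
        }
        if pred.any() and gt.any():
            sd = surface_distances(pred, gt, spacing)
            row["hausdorff_mm"] = hausdorff(sd)
            row["assd_mm"] = assd(sd)
        else:
            row["hausdorff_mm"] = float("nan")
            row["assd_mm"] = float("nan")
        _, row["vvc"] = vvc(stack, threshold, tract=n)
        row["mean_pass_dice"] = mean_pass_dice(stack, gt, threshold, tract=n)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) per metric across subject x tract rows."""
    metrics = [
        "dice", "sensitivity", "specificity", "hausdorff_mm", "assd_mm",
        "vvc", "mean_pass_dice",
    ]
    agg = report[metrics].agg(["mean", "std"]).T
    agg.columns = ["mean", "sd"]
    return agg
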