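"""Quantile-volume calibration of stochastic segmentations.

From T stochastic passes, each voxel has an empirical distribution of
predicted probabilities. Taking the per-voxel quantile at level k and
summing over voxels gives a "soft volume" V_k; sweeping k in
{0, 1/T, ..., 1} yields a monotone quantile-volume curve whose span is a
volume confidence interval.

Uncalibrated curves rarely cover ground-truth volumes at nominal rates
(stochastic passes are typically over-confident and biased), so a
per-tract monotone remapping of quantile levels is fitted on validation
subjects: each validation ground truth is located on its own curve
(its *coverage level*), and nominal levels are sent through the empirical
quantile function of those coverage levels. On the validation
distribution the remapped coverage levels are uniform on [0, 1], i.e. a
nominal central interval covers the stated proportion of ground truths.

Both the coverage levels and the fitted map extend linearly beyond [0, 1]
using the end-segment slope of the curve (a linear scaling of the
interpolation at the boundaries): a ground truth lying outside the raw
volume range receives an extrapolated level, and the calibrated curve may
report volumes beyond the raw [V_0, V_1] span. Without this, a systematic
volume bias larger than the stack's spread would be uncorrectable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError
from .inference import ProbabilityStack


def _interp_linear_extrap(x, xp, fp):
    """np.interp with linear extrapolation from the end segments."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(xp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    y = np.interp(x, xp, fp)
    if xp.size >= 2:
        lo_slope_den = xp[1] - xp[0]
        hi_slope_den = xp[-1] - xp[-2]
        below = x < xp[0]
        above = x > xp[-1]
        if lo_slope_den > 0:
            y = np.where(below, fp[0] + (x - xp[0]) * (fp[1] - fp[0]) / lo_slope_den, y)
        if hi_slope_den > 0:
            y = np.where(
                above, fp[-1] + (x - xp[-1]) * (fp[-1] - fp[-2]) / hi_slope_den, y
            )
    return y if y.ndim else float(y)


@dataclass
class QuantileVolumeCurve:
    """Soft volumes V_k at quantile levels k, per tract."""

    levels: np.ndarray  # (K,) in [0, 1], increasing
    volumes: np.ndarray  # (K,) mm^3 (or voxels), non-decreasing
    tract_id: int = 0
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.levels.shape != self.volumes.shape or self.levels.ndim != 1:
            raise ShapeError("levels and volumes must be equal-length 1D arrays")
        if self.levels.size == 0:
            raise ConfigurationError("empty curve")
        if np.any(np.diff(self.levels) < 0):
            raise ConfigurationError("levels must be non-decreasing")
        if np.any(np.diff(self.volumes) < -1e-9):
            raise ConfigurationError("volumes must be non-decreasing in level")

    def volume_at(self, level) -> np.ndarray:
        """Piecewise-linear volume at a level; extrapolates outside [0, 1]."""
        return _interp_linear_extrap(level, self.levels, self.volumes)


@dataclass
class CalibrationMap:
    """Monotone remapping of nominal quantile levels, fitted per tract.

    Knots hold the empirical quantile function of validation coverage
    levels; evaluation extrapolates linearly beyond the knot range, so
    calibrated levels may leave [0, 1] (the curve is then evaluated by
    linear extension of its end segments).
    """

    nominal: np.ndarray  # (K,) knot positions in [0, 1]
    calibrated: np.ndarray  # (K,) remapped levels (may exceed [0, 1])
    tract_id: int = 0
    n_validation: int = 0
    degenerate: bool = False  # all validation coverage levels identical

    def __post_init__(self) -> None:
        self.nominal = np.asarray(self.nominal, dtype=float)
        self.calibrated = np.asarray(self.calibrated, dtype=float)
        if np.any(np.diff(self.nominal) < 0) or np.any(
            np.diff(self.calibrated) < -1e-12
        ):
            raise ConfigurationError("calibration knots must be non-decreasing")

    def __call__(self, q) -> np.ndarray:
        return _interp_linear_extrap(np.clip(q, 0.0, 1.0), self.nominal, self.calibrated)

    @classmethod
    def identity(cls, tract_id: int = 0) -> "CalibrationMap":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]), tract_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tract_id": int(self.tract_id),
                "nominal": self.nominal.tolist(),
                "calibrated": self.calibrated.tolist(),
                "n_validation": int(self.n_validation),
                "degenerate": bool(self.degenerate),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "CalibrationMap":
        d = json.loads(s)
        return cls(
            np.asarray(d["nominal"]),
            np.asarray(d["calibrated"]),
            d.get("tract_id", 0),
            d.get("n_validation", 0),
            d.get("degenerate", False),
        )


def default_levels(t: int) -> np.ndarray:
    """The T+1 levels {0, 1/T, ..., 1} for a stack of T passes."""
    return np.linspace(0.0, 1.0, t + 1)


def voxel_quantiles(
    stack: ProbabilityStack, levels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel, per-class empirical quantiles of the T pass probabilities.

    Linear interpolation of order statistics; level 0 is the minimum and
    level 1 the maximum. Returns (levels, maps) with maps of shape
    (K, X, Y, Z, N).
    """
    if levels is None:
        levels = default_levels(stack.n_passes)
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0) or np.any(levels > 1) or np.any(np.diff(levels) < 0):
        raise ValueError("levels must be sorted within [0, 1]")
    maps = np.quantile(stack.probs, levels, axis=0, method="linear")
    return levels, maps


def quantile_volume_curve(
    levels: np.ndarray,
    maps: np.ndarray,
    voxel_volume: float = 1.0,
) -> list[QuantileVolumeCurve]:
    """Sum each quantile map over voxels: V_k = voxel_volume * sum_j w_kj.

    ``maps`` is (K, X, Y, Z, N) from :func:`voxel_quantiles` (or (K, ...)
    for a single tract). Returns one curve per tract channel.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[:, :, None]
    if maps.shape[0] != len(levels):
        raise ShapeError("first axis of maps must match levels")
    n = maps.shape[-1]
    flat = maps.reshape(maps.shape[0], -1, n)
    volumes = flat.sum(axis=1) * voxel_volume  # (K, N)
    return [
        QuantileVolumeCurve(
            np.asarray(levels), volumes[:, t], tract_id=t, voxel_volume=voxel_volume
        )
        for t in range(n)
    ]


def coverage_level(
    curve: QuantileVolumeCurve, v_ref: float, extend: bool = False
) -> float:
    """Level at which the piecewise-linear curve crosses a reference volume.

    With ``extend=False`` (default) the level is clipped to [0, 1]; with
    ``extend=True`` it continues linearly along the end segments, so a
    reference volume outside the curve's range gets a level outside
    [0, 1] (used when fitting calibration). On plateaus the lowest
    crossing level is returned, making the operation deterministic.
    """
    v = curve.volumes
    lev = curve.levels
    if v_ref < v[0] or v_ref > v[-1]:
        if not extend or v.size < 2:
            return 0.0 if v_ref < v[0] else 1.0
        if v_ref < v[0]:
            slope = v[1] - v[0]
            rise = lev[1] - lev[0]
            if slope <= 0:
                return float(lev[0])
            return float(lev[0] + (v_ref - v[0]) * rise / slope)
        slope = v[-1] - v[-2]
        rise = lev[-1] - lev[-2]
        if slope <= 0:
            return float(lev[-1])
        return float(lev[-1] + (v_ref - v[-1]) * rise / slope)
    i = int(np.searchsorted(v, v_ref, side="left"))
    if v[i] == v_ref:
        return float(lev[i])
    # interpolate on the segment (i-1, i); v[i-1] < v_ref < v[i]
    frac = (v_ref - v[i - 1]) / (v[i] - v[i - 1])
    return float(lev[i - 1] + frac * (lev[i] - lev[i - 1]))


def fit_calibration(
    validation: list[tuple[QuantileVolumeCurve, float]], tract_id: int | None = None
) -> CalibrationMap:
    """Fit the per-tract level remapping on validation subjects.

    Computes each subject's (extended) coverage level
    u_s = coverage_level(curve, v_gt, extend=True) and builds the
    empirical quantile function of {u_s} with knots at plotting positions
    i/(n+1). Applying the map makes validation coverage levels uniform on
    [0, 1]; coverage levels outside [0, 1] (ground truths beyond the raw
    volume range) pull the map's end knots outward, which is what lets the
    calibrated curve correct a systematic volume bias.
    """
    if not validation:
        raise ConfigurationError("need at least one validation subject")
    if tract_id is None:
        tract_id = validation[0][0].tract_id
    u = np.sort([coverage_level(c, v, extend=True) for c, v in validation])
    n = u.size
    degenerate = bool(n >= 2 and np.allclose(u, u[0]))
    if degenerate:
        warnings.warn(
            "all validation coverage levels identical; calibration map "
            "degenerates to a step",
            stacklevel=2,
        )
    nominal = np.arange(1, n + 1) / (n + 1)
    return CalibrationMap(
        nominal, u, tract_id=tract_id, n_validation=n, degenerate=degenerate
    )


def apply_calibration(
    curve: QuantileVolumeCurve, cal: CalibrationMap
) -> QuantileVolumeCurve:
    """Evaluate the curve at remapped levels: V'_k = V(map(k)).

    Remapped levels outside [0, 1] read the curve through linear extension
    of its end segments (the volume-axis scaling of the calibration).
    """
    if curve.tract_id != cal.tract_id:
        raise ConfigurationError(
            f"curve tract {curve.tract_id} vs map tract {cal.tract_id}"
        )
    remapped = cal(curve.levels)
    volumes = curve.volume_at(remapped)
    volumes = np.maximum.accumulate(volumes)  # guard fp monotonicity
    return QuantileVolumeCurve(
        curve.levels.copy(), volumes, curve.tract_id, curve.voxel_volume
    )


def min_volume_difference(curve: QuantileVolumeCurve, v_gt: float) -> float:
    """Smallest |V_k - v_gt| over the curve's levels."""
    return float(np.abs(curve.volumes - v_gt).min())
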