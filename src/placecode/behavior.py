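"""Pose smoothing, speed computation and movement-epoch masking.

Position and speed are smoothed with a centered moving average over a 0.5 s
window.  At the 7.5 Hz neural timebase 0.5 s is 3.75 samples; the window is
rounded to 4 samples (~0.533 s) and truncated at the series edges so the
output length never changes.  Movement epochs are samples where *both* the
nose and the tailbase move strictly faster than the threshold (default
3 cm/s); the tailbase is the mapping point used for position throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import POSE_COLUMNS, AnalysisConfig, Session

BODY_POINTS = ("nose", "ear", "tail")


@dataclass
class BehaviorSeries:
    """Smoothed kinematics for one session on the neural timebase."""

    pose: np.ndarray          # samples x 6, smoothed, columns as POSE_COLUMNS
    speeds: dict[str, np.ndarray]  # cm/s per body point
    movement_mask: np.ndarray      # bool per sample
    path_length_cm: float
    sample_rate_hz: float

    @property
    def x(self) -> np.ndarray:
        """Mapping-point (tailbase) x position in cm."""
        return self.pose[:, POSE_COLUMNS.index("tail_x")]

    @property
    def y(self) -> np.ndarray:
        return self.pose[:, POSE_COLUMNS.index("tail_y")]

    @property
    def speed(self) -> np.ndarray:
        """Mapping-point (tailbase) speed in cm/s."""
        return self.speeds["tail"]


def _window_samples(window_s: float, sample_rate_hz: float) -> int:
    return int(round(window_s * sample_rate_hz))


def smooth_pose(pose: np.ndarray, window_s: float, sample_rate_hz: float) -> np.ndarray:
    """Centered moving average per column, truncated at the edges."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    pose = np.asarray(pose, dtype=float)
    w = _window_samples(window_s, sample_rate_hz)
    if w <= 1:
        warnings.warn("smoothing window shorter than one sample; returning input")
        return pose.copy()
    return _moving_average(pose, w)


def _moving_average(arr: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average along axis 0 with edge truncation.

    For even w the window covers ``w//2`` samples back and ``w//2 - 1``
    forward, matching a trailing-center convention.
    """
    arr2 = np.atleast_2d(arr.T).T if arr.ndim == 1 else arr
    n = arr2.shape[0]
    csum = np.zeros((n + 1,) + arr2.shape[1:])
    np.cumsum(arr2, axis=0, out=csum[1:])
    back = w // 2
    fwd = w - back - 1
    idx = np.arange(n)
    lo = np.maximum(idx - back, 0)
    hi = np.minimum(idx + fwd, n - 1) + 1
    out = (csum[hi] - csum[lo]) / (hi - lo).reshape(-1, *([1] * (arr2.ndim - 1)))
    return out if arr.ndim > 1 else out[:, 0] if out.ndim == 2 else out


def compute_speed(xy: np.ndarray, sample_rate_hz: float, window_s: float = 0.5) -> np.ndarray:
    """Instantaneous speed (cm/s) from a smoothed xy series.

    Speed at sample t is the Euclidean step from t-1 to t times the sample
    rate; the first sample copies the second.  The speed series is smoothed
    with the same moving-average window as the pose.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need at least two samples")
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = np.empty(xy.shape[0])
    speed[1:] = step * sample_rate_hz
    speed[0] = speed[1]
    w = _window_samples(window_s, sample_rate_hz)
    if w > 1:
        speed = _moving_average(speed, w)
    return speed


def movement_mask(
    speeds: dict[str, np.ndarray],
    threshold_cm_s: float,
    removed: np.ndarray | None = None,
) -> np.ndarray:
    """True where both nose and tailbase speed strictly exceed the threshold."""
    for name in ("nose", "tail"):
        if name not in speeds:
            raise KeyError(f"missing body point speed: {name!r}")
    mask = (speeds["nose"] > threshold_cm_s) & (speeds["tail"] > threshold_cm_s)
    if removed is not None:
        mask = mask & np.asarray(removed, dtype=bool)
    return mask


def analyze_behavior(session: Session, config: AnalysisConfig | None = None) -> BehaviorSeries:
    """Smooth the pose, derive per-point speeds and the movement mask."""
    config = config or AnalysisConfig()
    smoothed = smooth_pose(session.pose, config.pose_smooth_window_s, session.sample_rate_hz)
    speeds = {}
    for i, name in enumerate(BODY_POINTS):
        xy = smoothed[:, 2 * i : 2 * i + 2]
        speeds[name] = compute_speed(
            xy, session.sample_rate_hz, config.pose_smooth_window_s
        )
    mask = movement_mask(speeds, config.speed_threshold_cm_s, session.kept_samples())
    tail = smoothed[:, 4:6]
    path = float(np.linalg.norm(np.diff(tail, axis=0), axis=1).sum())
    return BehaviorSeries(
        pose=smoothed,
        speeds=speeds,
        movement_mask=mask,
        path_length_cm=path,
        sample_rate_hz=session.sample_rate_hz,
    )
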