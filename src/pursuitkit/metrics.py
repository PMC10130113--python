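"""Offline scoring of touch traces.

Raw touch coordinates are smoothed with a zero-phase (forward–backward)
Butterworth low-pass filter — 8 Hz cut-off, 4th order by default — to
damp sensor noise faster than any fingertip movement; no outlier
removal or resampling is performed, since abrupt features (slips, jerky
corrections) are themselves informative.  Two per-frame offset metrics
are then computed against the moving target:

* **directional offset** — the absolute difference between the
  tangential (movement-direction) angles of the touch and the target,
  wrapped into [0, 180] degrees.  It scores *how well the direction of
  the target's motion is followed*, independent of where on the screen
  the finger is.
* **spatial offset** — the Euclidean distance between the touch
  position and the target center, in millimetres.

Target angles come analytically from the trajectory construction;
touch angles are estimated by central differences on the filtered
positions, with frames below a minimum speed flagged invalid (the
direction of a stationary finger is undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from pursuitkit.acquisition import AlignmentError, ResetEvent, TouchTrace
from pursuitkit.stimulus import PIXEL_PITCH_MM, Trajectory, wrap_angle_deg

#: Default minimum fingertip speed (mm/s) for a defined movement direction.
MIN_SPEED_MM_S = 2.0


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass design."""

    cutoff_hz: float = 8.0
    order: int = 4

    def __post_init__(self):
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, frame_rate: float):
        if not self.cutoff_hz < frame_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist "
                f"({frame_rate / 2} Hz)"
            )
        return signal.butter(
            self.order, self.cutoff_hz, btype="low", fs=frame_rate, output="sos"
        )


@dataclass(frozen=True)
class OffsetSeries:
    """Per-frame offsets of one trace against one trajectory."""

    trajectory_label: str
    directional_offset_deg: np.ndarray  # [0, 180], NaN where invalid
    spatial_offset_mm: np.ndarray  # >= 0, NaN where invalid
    directional_valid: np.ndarray  # bool
    spatial_valid: np.ndarray  # bool
    filtered: bool = True  # False when the segment was too short to filter


@dataclass(frozen=True)
class TrajectorySummary:
    """Mean offsets over valid frames for one trajectory attempt."""

    trajectory_label: str
    mean_directional_offset_deg: float
    mean_spatial_offset_mm: float
    n_valid_directional: int
    n_valid_spatial: int
    n_resets: int = 0

    @property
    def n_valid_frames(self) -> int:
        return min(self.n_valid_directional, self.n_valid_spatial)


def lowpass_filter(
    positions: np.ndarray,
    spec: FilterSpec | None = None,
    frame_rate: float = 60.0,
) -> tuple[np.ndarray, bool]:
    """Forward–backward Butterworth filtering of an (n, 2) position series.

    x and y are filtered independently; the two passes cancel the phase
    shift, so the squared magnitude response applies.  Returns the
    filtered array and a flag that is False when the segment was too
    short to pad, in which case raw positions are passed through with a
    warning.
    """
    spec = spec or FilterSpec()
    positions = np.asarray(positions, dtype=float)
    sos = spec.sos(frame_rate)
    padlen = 3 * (2 * sos.shape[0] + 1)
    n = positions.shape[0]
    if n <= padlen:
        warnings.warn(
            f"segment of {n} frames too short to filter (needs > {padlen}); "
            "passing raw positions through",
            stacklevel=2,
        )
        return positions.copy(), False
    return signal.sosfiltfilt(sos, positions, axis=0), True


def tangential_angles(
    positions: np.ndarray,
    frame_rate: float = 60.0,
    min_speed_mm_s: float = MIN_SPEED_MM_S,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame movement direction (degrees) with validity flags.

    Central differences in the interior, one-sided at the ends.  A
    frame is invalid when its instantaneous speed is below
    ``min_speed_mm_s`` (direction undefined) or any sample entering the
    difference is NaN.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 frames to estimate direction")
    vel = np.gradient(positions, axis=0) * frame_rate  # px/s
    speed_mm_s = np.hypot(vel[:, 0], vel[:, 1]) * pixel_pitch_mm
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(speed_mm_s) & (speed_mm_s >= min_speed_mm_s)
    angles = np.degrees(np.arctan2(vel[:, 1], vel[:, 0]))
    angles = np.where(valid, wrap_angle_deg(angles), np.nan)
    return angles, valid


def directional_offset(
    touch_angles: np.ndarray, target_angles: np.ndarray
) -> np.ndarray:
    """Absolute angular difference in [0, 180] degrees, NaN-propagating.

    ``offset = min(|dtheta|, 360 - |dtheta|)`` — the smaller of the two
    arcs between the movement directions.
    """
    touch_angles = np.asarray(touch_angles, dtype=float)
    target_angles = np.asarray(target_angles, dtype=float)
    if touch_angles.shape != target_angles.shape:
        raise AlignmentError(
            f"angle series lengths differ: {touch_angles.shape} vs "
            f"{target_angles.shape}"
        )
    diff = np.abs(touch_angles - target_angles) % 360.0
    return np.minimum(diff, 360.0 - diff)


def spatial_offset(
    touch_positions: np.ndarray,
    target_positions: np.ndarray,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
) -> np.ndarray:
    """Euclidean touch–target distance per frame, converted px -> mm."""
    touch_positions = np.asarray(touch_positions, dtype=float)
    target_positions = np.asarray(target_positions, dtype=float)
    if touch_positions.shape != target_positions.shape:
        raise AlignmentError(
            f"position series shapes differ: {touch_positions.shape} vs "
            f"{target_positions.shape}"
        )
    delta = touch_positions - target_positions
    return np.hypot(delta[..., 0], delta[..., 1]) * pixel_pitch_mm


def compute_offsets(
    trace: TouchTrace,
    traj: Trajectory,
    filter_spec: FilterSpec | None = None,
    min_speed_mm_s: float = MIN_SPEED_MM_S,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
) -> OffsetSeries:
    """Filter a trace and compute both offset series against a trajectory.

    Inactive-touch frames are excluded (not interpolated).  The touch
    movement direction is estimated from the *filtered* positions; the
    target direction is the trajectory's analytic tangent.
    """
    if trace.n_frames != traj.n_frames:
        raise AlignmentError(
            f"trace has {trace.n_frames} frames, trajectory {traj.label!r} "
            f"has {traj.n_frames}"
        )
    active = np.asarray(trace.active, dtype=bool)
    touch = trace.touch.copy()
    filtered_ok = True
    # filter each contiguous active segment independently; gaps stay NaN
    segments = _contiguous_runs(active)
    filtered = np.full_like(touch, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lo, hi in segments:
            seg, ok = lowpass_filter(touch[lo:hi], filter_spec, trace.frame_rate)
            filtered[lo:hi] = seg
            filtered_ok = filtered_ok and ok
    touch_angles, touch_valid = tangential_angles(
        filtered, trace.frame_rate, min_speed_mm_s, pixel_pitch_mm
    )
    dir_off = directional_offset(touch_angles, traj.frame_angles)
    dir_valid = touch_valid & active & np.isfinite(dir_off)
    dir_off = np.where(dir_valid, dir_off, np.nan)
    spa_off = spatial_offset(filtered, traj.frames, pixel_pitch_mm)
    spa_valid = active & np.isfinite(spa_off)
    spa_off = np.where(spa_valid, spa_off, np.nan)
    return OffsetSeries(
        trajectory_label=traj.label,
        directional_offset_deg=dir_off,
        spatial_offset_mm=spa_off,
        directional_valid=dir_valid,
        spatial_valid=spa_valid,
        filtered=filtered_ok,
    )


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index ranges of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def summarize(
    offsets: OffsetSeries,
    resets: list[ResetEvent] | None = None,
    statistic: str = "mean",
) -> TrajectorySummary | None:
    """Aggregate an offset series over its valid frames.

    The per-trajectory aggregate is the arithmetic mean of valid
    per-frame offsets (``statistic="median"`` is available for
    sensitivity analyses).  Returns None when no frame is valid; the
    missing summary propagates as missing data downstream.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    agg = np.nanmean if statistic == "mean" else np.nanmedian
    n_dir = int(offsets.directional_valid.sum())
    n_spa = int(offsets.spatial_valid.sum())
    if n_dir == 0 or n_spa == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_dir = float(agg(offsets.directional_offset_deg))
        mean_spa = float(agg(offsets.spatial_offset_mm))
    return TrajectorySummary(
        trajectory_label=offsets.trajectory_label,
        mean_directional_offset_deg=mean_dir,
        mean_spatial_offset_mm=mean_spa,
        n_valid_directional=n_dir,
        n_valid_spatial=n_spa,
        n_resets=len(resets) if resets else 0,
    )


def score_session(
    record,
    battery: dict[str, Trajectory],
    filter_spec: FilterSpec | None = None,
    statistic: str = "mean",
    detect_reset_events: bool = True,
) -> dict[str, TrajectorySummary | None]:
    """Score every trace in a session against its battery trajectory."""
    from pursuitkit.acquisition import assume_constant_rate, detect_resets

    summaries: dict[str, TrajectorySummary | None] = {}
    for label, trace in record.traces.items():
        if label not in battery:
            raise KeyError(f"trace {label!r} has no trajectory in the battery")
        traj = battery[label]
        trace = assume_constant_rate(trace)
        resets = detect_resets(trace, traj) if detect_reset_events else []
        offsets = compute_offsets(trace, traj, filter_spec)
        summaries[label] = summarize(offsets, resets, statistic)
    return summaries
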