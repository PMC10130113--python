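"""Session protocol logic and touch-log I/O.

The device registers the fingertip at 60 Hz while a target moves along
a trajectory.  This module holds the session-level protocol rules (the
too-far-for-too-long level reset) and the on-disk session format: one
CSV per trajectory attempt plus a JSON manifest per session.

The reset rule mirrors the game directive: if the touch stays more
than 9 mm from the target center for 1.7 s, the level resets.  Resets
are recorded as events; scoring continues on the full trace.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath

import numpy as np

from pursuitkit.stimulus import PIXEL_PITCH_MM, DEFAULT_FRAME_RATE, Trajectory

SESSION_FORMAT = "pursuitkit-session/1"

#: Reset rule defaults: distance threshold (mm) and dwell (s).
RESET_DIST_MM = 9.0
RESET_DWELL_S = 1.7

_TRACE_COLUMNS = (
    "frame",
    "t_ms",
    "target_x_px",
    "target_y_px",
    "touch_x_px",
    "touch_y_px",
    "active",
)


class SessionParseError(ValueError):
    """Raised when a session file cannot be parsed."""


class AlignmentError(ValueError):
    """Raised when a trace and a trajectory disagree in length or rate."""


@dataclass(frozen=True)
class TouchTrace:
    """Per-frame touch samples aligned to one trajectory attempt.

    Positions are NaN on frames where the touch is inactive (finger
    lifted).  ``target`` retains the rendered target positions so a log
    is self-contained on disk.
    """

    t_ms: np.ndarray
    touch: np.ndarray  # (n, 2) px, NaN when inactive
    active: np.ndarray  # (n,) bool
    trajectory_label: str
    frame_rate: float = DEFAULT_FRAME_RATE
    target: np.ndarray | None = None  # (n, 2) px as displayed
    raw_t_ms: np.ndarray | None = None  # original timestamps, if regularized

    def __post_init__(self):
        if np.any(np.diff(self.t_ms) < 0):
            raise ValueError("touch-trace timestamps must be non-decreasing")
        if self.touch.shape != (self.t_ms.size, 2):
            raise ValueError("touch array must be (n_frames, 2)")
        inactive = ~np.asarray(self.active, dtype=bool)
        object.__setattr__(self, "touch", np.where(inactive[:, None], np.nan, self.touch))

    @property
    def n_frames(self) -> int:
        return int(self.t_ms.size)

    def timestamp_jitter_ms(self) -> float:
        """SD of the frame interval (ms); ~0 for a regular clock."""
        if self.n_frames < 3:
            return 0.0
        return float(np.std(np.diff(self.t_ms)))


@dataclass(frozen=True)
class ResetEvent:
    """A completed too-far dwell that reset the game level."""

    trajectory_label: str
    trigger_frame: int
    dwell_s: float


@dataclass
class SessionRecord:
    """One testing occasion for one participant."""

    participant_id: str
    session_index: int
    age_years: float
    traces: dict[str, TouchTrace] = field(default_factory=dict)
    resets: list[ResetEvent] = field(default_factory=list)
    battery_hash: str | None = None

    def __post_init__(self):
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")
        if not 3.0 <= self.age_years <= 18.0:
            warnings.warn(
                f"age {self.age_years} y outside the expected 3-18 range",
                stacklevel=2,
            )


def assume_constant_rate(trace: TouchTrace) -> TouchTrace:
    """Replace timestamps by a uniform grid at the nominal frame rate.

    Touch screens show small timestamp jitter (SD on the order of
    1.7 ms); positions are *not* resampled — a constant frame rate is
    assumed and only the clock is regularized.  The original timestamps
    are retained in ``raw_t_ms``.
    """
    uniform = np.arange(trace.n_frames) * 1000.0 / trace.frame_rate
    raw = trace.raw_t_ms if trace.raw_t_ms is not None else trace.t_ms
    return replace(trace, t_ms=uniform, raw_t_ms=raw)


def detect_resets(
    trace: TouchTrace,
    traj: Trajectory,
    dist_threshold_mm: float = RESET_DIST_MM,
    dwell_s: float = RESET_DWELL_S,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
    inactive_counts_as_far: bool = True,
) -> list[ResetEvent]:
    """Apply the level-reset rule to one trace.

    A reset fires at the first frame where the touch–target distance
    has exceeded ``dist_threshold_mm`` for ``dwell_s`` of consecutive
    elapsed time; the dwell clock restarts after each reset and resets
    to zero whenever the distance drops back within threshold.  An
    inactive-touch frame counts as too far by default (the finger is
    off the screen).  Distances are measured on unfiltered positions:
    the rule ran in real time on the device, before any offline
    smoothing.
    """
    if not (dist_threshold_mm > 0 and dwell_s > 0):
        raise ValueError("reset thresholds must be positive")
    if trace.n_frames != traj.n_frames:
        raise AlignmentError(
            f"trace has {trace.n_frames} frames but trajectory "
            f"{traj.label!r} has {traj.n_frames}"
        )
    delta = trace.touch - traj.frames
    dist_mm = np.hypot(delta[:, 0], delta[:, 1]) * pixel_pitch_mm
    too_far = dist_mm > dist_threshold_mm
    if inactive_counts_as_far:
        too_far = too_far | ~np.asarray(trace.active, dtype=bool)
    else:
        too_far = too_far & np.asarray(trace.active, dtype=bool)

    events: list[ResetEvent] = []
    start: int | None = None
    for i, far in enumerate(too_far):
        if not far:
            start = None
            continue
        if start is None:
            start = i
        elapsed = (i - start) / trace.frame_rate
        if elapsed >= dwell_s:
            events.append(
                ResetEvent(
                    trajectory_label=traj.label,
                    trigger_frame=i,
                    dwell_s=elapsed,
                )
            )
            start = None  # dwell clock restarts after a reset
    return events


# ---------------------------------------------------------------------------
# On-disk format: per-trajectory CSV + session manifest JSON
# ---------------------------------------------------------------------------

def _format_float(x: float) -> str:
    return "nan" if np.isnan(x) else repr(float(x))


def write_session(record: SessionRecord, path) -> FilePath:
    """Write a session directory: ``manifest.json`` + one CSV per trace.

    The round trip through :func:`read_session` is lossless (floats are
    written with full precision).
    """
    out = FilePath(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": SESSION_FORMAT,
        "participant_id": record.participant_id,
        "session_index": record.session_index,
        "age_years": record.age_years,
        "battery_hash": record.battery_hash,
        "trajectories": {
            label: {"frame_rate": tr.frame_rate, "n_frames": tr.n_frames}
            for label, tr in record.traces.items()
        },
        "resets": [
            {
                "trajectory_label": ev.trajectory_label,
                "trigger_frame": ev.trigger_frame,
                "dwell_s": ev.dwell_s,
            }
            for ev in record.resets
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for label, tr in record.traces.items():
        target = tr.target if tr.target is not None else np.full_like(tr.touch, np.nan)
        with open(out / f"{label}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_TRACE_COLUMNS)
            for i in range(tr.n_frames):
                writer.writerow(
                    [
                        i,
                        _format_float(tr.t_ms[i]),
                        _format_float(target[i, 0]),
                        _format_float(target[i, 1]),
                        _format_float(tr.touch[i, 0]),
                        _format_float(tr.touch[i, 1]),
                        int(tr.active[i]),
                    ]
                )
    return out


def _read_trace_csv(path: FilePath, label: str, frame_rate: float) -> TouchTrace:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SessionParseError(f"{path}: empty trace file")
        if tuple(header) != _TRACE_COLUMNS:
            missing = set(_TRACE_COLUMNS) - set(header)
            raise SessionParseError(
                f"{path}: bad header; missing columns {sorted(missing)}"
                if missing
                else f"{path}: unexpected column order {header}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_TRACE_COLUMNS):
                raise SessionParseError(
                    f"{path}:{lineno}: expected {len(_TRACE_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise SessionParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise SessionParseError(f"{path}: no data rows")
    arr = np.array(rows)
    return TouchTrace(
        t_ms=arr[:, 1],
        touch=arr[:, 4:6],
        active=arr[:, 6].astype(bool),
        trajectory_label=label,
        frame_rate=frame_rate,
        target=arr[:, 2:4],
    )


def read_session(path) -> SessionRecord:
    """Read a session directory written by :func:`write_session`."""
    root = FilePath(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise SessionParseError(f"{root}: no manifest.json")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"{manifest_path}: invalid JSON ({exc})") from None
    fmt = manifest.get("format")
    if fmt != SESSION_FORMAT:
        raise SessionParseError(
            f"{manifest_path}: format {fmt!r} != expected {SESSION_FORMAT!r}"
        )
    traces = {}
    for label, meta in manifest.get("trajectories", {}).items():
        traces[label] = _read_trace_csv(
            root / f"{label}.csv", label, float(meta["frame_rate"])
        )
    record = SessionRecord(
        participant_id=manifest["participant_id"],
        session_index=int(manifest["session_index"]),
        age_years=float(manifest["age_years"]),
        traces=traces,
        resets=[
            ResetEvent(
                trajectory_label=ev["trajectory_label"],
                trigger_frame=int(ev["trigger_frame"]),
                dwell_s=float(ev["dwell_s"]),
            )
            for ev in manifest.get("resets", [])
        ],
        battery_hash=manifest.get("battery_hash"),
    )
    return record
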