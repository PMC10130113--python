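"""Stimulus battery generation.

Path *shapes* are built from an array of tangential angles: a periodic
modification of a normalized tunable sigmoid defines the angle as a
function of arc length, and the cumulative sum of its cosine and sine
traces out the planar path.  Path *timing* comes from one of three
motion profiles: the minimum-jerk quintic (straight horizontal line),
constant speed (tilted lines), or a speed–curvature power law
(zigzags and spirals), all sampled at the 60 Hz display frame rate.

Coordinates follow the touch-screen convention: pixels, origin at the
top-left corner, y increasing downward.  Angles are reported in degrees
wrapped to (-180, 180]; a positive angle therefore turns *downward* on
screen.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Physical pixel pitch of the 155 mm wide, 800 px wide display.
PIXEL_PITCH_MM: float = 155.0 / 800.0

#: Display refresh / touch sampling rate in Hz.
DEFAULT_FRAME_RATE: float = 60.0

#: Screen size in pixels (width, height) in landscape orientation.
SCREEN_PX: tuple[int, int] = (800, 480)

#: Curvature floor (1/px) below which the power-law speed is clamped,
#: preventing unbounded speed on straight segments.
CURVATURE_FLOOR: float = 1e-6

_SHAPE_FAMILIES = ("hline", "tlineR", "tlineL", "zigzag", "spiral")
_PROFILE_FAMILIES = ("minimum_jerk", "constant_speed", "power_law")

BATTERY_LABELS = (
    "hline",
    "tlineR",
    "tlineL",
    "zigzagA",
    "zigzagB",
    "zigzagC",
    "spiralA",
    "spiralB",
    "spiralC",
)


class ConfigError(ValueError):
    """Raised for invalid or incomplete battery / shape configuration."""


def tunable_sigmoid(x, k: float):
    """Normalized tunable sigmoid.

    ``f(x, k) = (x - k*x) / (k - 2*k*|x| + 1)`` maps [-1, 1] onto
    [-1, 1], is odd in ``x`` and monotone non-decreasing for any fixed
    tuning parameter ``k`` in (-1, 1).  ``k = 0`` is the identity;
    ``k -> 1`` approaches a step (sharp transitions), ``k -> -1``
    approaches a linear-threshold ramp (flattened center).

    Parameters
    ----------
    x : float or array_like
        Normalized abscissa in [-1, 1].
    k : float
        Tuning parameter, strictly inside (-1, 1).

    Returns
    -------
    float or ndarray
        Normalized ordinate in [-1, 1], same shape as ``x``.
    """
    if not -1.0 < k < 1.0:
        raise ValueError(f"sigmoid tuning parameter k={k!r} outside (-1, 1)")
    x_arr = np.asarray(x, dtype=float)
    if np.any(np.abs(x_arr) > 1.0 + 1e-12):
        raise ValueError(f"sigmoid abscissa x={x!r} outside [-1, 1]")
    x_arr = np.clip(x_arr, -1.0, 1.0)
    out = (x_arr - k * x_arr) / (k - 2.0 * k * np.abs(x_arr) + 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PathSpec:
    """Geometric description of one path shape (no timing).

    ``extent`` is the total arc length of the path in pixels; ``step``
    the arc-length increment between consecutive samples.  Shaping
    parameters depend on the family: zigzags take ``periods``,
    ``amplitude_deg`` and ``sigmoid_k``; spirals take ``turns`` and
    ``inner_frac`` (fraction of the winding rate already accumulated at
    the start, which keeps the innermost curvature finite).
    """

    shape_family: str
    extent: float
    step: float = 1.0
    shaping: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape_family not in _SHAPE_FAMILIES:
            raise ConfigError(
                f"unknown shape_family {self.shape_family!r}; "
                f"expected one of {_SHAPE_FAMILIES}"
            )
        if not self.extent > 0:
            raise ConfigError(f"extent must be > 0, got {self.extent}")
        if not self.step > 0:
            raise ConfigError(f"step must be > 0, got {self.step}")
        if self.shape_family == "zigzag":
            missing = {"periods", "amplitude_deg", "sigmoid_k"} - set(self.shaping)
            if missing:
                raise ConfigError(f"zigzag spec missing shaping keys: {sorted(missing)}")
            if not 0 < self.shaping["amplitude_deg"] < 90:
                raise ConfigError("zigzag amplitude_deg must be in (0, 90)")
            if not self.shaping["periods"] >= 1:
                raise ConfigError("zigzag periods must be >= 1")
        if self.shape_family == "spiral":
            if "turns" not in self.shaping:
                raise ConfigError("spiral spec missing shaping key: ['turns']")
            if not self.shaping["turns"] > 1:
                raise ConfigError("spiral turns must exceed 1 (total turning > 360 deg)")


@dataclass(frozen=True)
class Path:
    """Arc-length-ordered planar curve with differential geometry.

    Attributes
    ----------
    points : (n, 2) ndarray
        Sample coordinates in pixels.
    tangent_angle : (n,) ndarray
        Tangential angle in degrees, wrapped to (-180, 180].
    curvature : (n,) ndarray
        Unsigned curvature in 1/px, estimated from successive angle
        differences over the arc step.
    arc_length : (n,) ndarray
        Cumulative arc length in pixels, strictly increasing from 0.
    """

    points: np.ndarray
    tangent_angle: np.ndarray
    curvature: np.ndarray
    arc_length: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


def wrap_angle_deg(angle):
    """Wrap angles (degrees) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def _triangle_wave(cycles: np.ndarray) -> np.ndarray:
    # period 1, range [-1, 1], starts at 0 rising: tri(0)=0, tri(.25)=1,
    # tri(.5)=0, tri(.75)=-1
    return 1.0 - 4.0 * np.abs(cycles + 0.75 - np.floor(cycles + 1.25))


def build_angle_array(spec: PathSpec) -> np.ndarray:
    """Tangential-angle series (degrees) for a path specification.

    The number of samples is chosen so that consecutive samples are
    ``spec.step`` pixels apart and the polyline's total arc length is
    exactly ``spec.extent``.
    """
    n = max(int(round(spec.extent / spec.step)) + 1, 2)
    tau = np.linspace(0.0, 1.0, n)
    if spec.shape_family == "hline":
        return np.zeros(n)
    if spec.shape_family == "tlineR":
        return np.full(n, 45.0)
    if spec.shape_family == "tlineL":
        return np.full(n, -45.0)
    if spec.shape_family == "zigzag":
        p = float(spec.shaping["periods"])
        amp = float(spec.shaping["amplitude_deg"])
        k = float(spec.shaping["sigmoid_k"])
        return amp * tunable_sigmoid(_triangle_wave(tau * p), k)
    # spiral: angle grows like the square root of arc length, the
    # winding of an Archimedean spiral traversed outward from the
    # center.  inner_frac > 0 starts slightly off-center so curvature
    # stays finite.
    turns = float(spec.shaping["turns"])
    t0 = float(spec.shaping.get("inner_frac", 0.02))
    return 360.0 * turns * (np.sqrt(t0 + (1.0 - t0) * tau) - np.sqrt(t0))


def path_from_angles(angles_deg, step: float = 1.0) -> Path:
    """Integrate a tangential-angle series into a planar path.

    Point ``i+1 = point i + step * (cos th_i, sin th_i)``, the cumulative
    sum of the cosine and sine of the angle array.  Curvature is the
    absolute angle increment per arc step.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size < 2:
        raise ValueError("need at least 2 tangential angles to build a path")
    if not step > 0:
        raise ValueError(f"step must be > 0, got {step}")
    rad = np.deg2rad(angles_deg)
    # heading over segment i is the angle at its starting sample
    dx = step * np.cos(rad[:-1])
    dy = step * np.sin(rad[:-1])
    points = np.zeros((angles_deg.size, 2))
    points[1:, 0] = np.cumsum(dx)
    points[1:, 1] = np.cumsum(dy)
    arc = step * np.arange(angles_deg.size, dtype=float)
    dtheta = np.gradient(np.unwrap(rad))
    curvature = np.abs(dtheta) / step
    return Path(
        points=points,
        tangent_angle=wrap_angle_deg(angles_deg),
        curvature=curvature,
        arc_length=arc,
    )


# ---------------------------------------------------------------------------
# Motion profiles
# ---------------------------------------------------------------------------

def _check_timing_args(total_length: float, average_speed: float, frame_rate: float):
    if not total_length > 0:
        raise ValueError(f"total_length must be > 0, got {total_length}")
    if not average_speed > 0:
        raise ValueError(f"average_speed must be > 0, got {average_speed}")
    if not frame_rate > 0:
        raise ValueError(f"frame_rate must be > 0, got {frame_rate}")


def minimum_jerk_profile(tau):
    """Normalized minimum-jerk displacement ``s(tau) = 10t^3 - 15t^4 + 6t^5``.

    The unique rest-to-rest quintic minimizing integrated squared jerk;
    speed is zero at both endpoints and peaks at 1.875x the mean.
    """
    t = np.asarray(tau, dtype=float)
    return t**3 * (10.0 - 15.0 * t + 6.0 * t * t)


def _frame_times(duration: float, frame_rate: float) -> np.ndarray:
    n_frames = max(int(round(duration * frame_rate)), 2)
    return np.arange(n_frames) / frame_rate


def minimum_jerk_timing(
    total_length: float, average_speed: float, frame_rate: float = DEFAULT_FRAME_RATE
) -> np.ndarray:
    """Per-frame normalized displacement fractions for min-jerk motion."""
    _check_timing_args(total_length, average_speed, frame_rate)
    duration = total_length / average_speed
    return minimum_jerk_profile(_frame_times(duration, frame_rate) / duration)


def constant_speed_timing(
    total_length: float, average_speed: float, frame_rate: float = DEFAULT_FRAME_RATE
) -> np.ndarray:
    """Per-frame normalized displacement fractions for uniform motion."""
    _check_timing_args(total_length, average_speed, frame_rate)
    duration = total_length / average_speed
    return _frame_times(duration, frame_rate) / duration


def power_law_timing(
    path: Path,
    average_speed: float,
    beta: float = 1.0 / 3.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> np.ndarray:
    """Per-frame displacement fractions under the speed–curvature power law.

    Instantaneous speed is ``v = g * kappa**(-beta)`` with the gain ``g``
    chosen so the realized mean speed over the traversal equals
    ``average_speed``; ``beta = 1/3`` is the classical two-thirds power
    law of curvilinear hand movement.  Curvature below
    :data:`CURVATURE_FLOOR` is clamped to the floor, so an (almost)
    straight path degrades gracefully to constant speed.
    """
    if not beta > 0:
        raise ValueError(f"power-law exponent beta must be > 0, got {beta}")
    _check_timing_args(path.total_length, average_speed, frame_rate)
    kappa = np.maximum(path.curvature, CURVATURE_FLOOR)
    if np.max(path.curvature) < CURVATURE_FLOOR:
        logger.info(
            "power-law timing on a zero-curvature path: falling back to constant speed"
        )
        return constant_speed_timing(path.total_length, average_speed, frame_rate)
    seg_kappa = 0.5 * (kappa[:-1] + kappa[1:])
    seg_len = np.diff(path.arc_length)
    # dt_j = seg_len * kappa^beta / g; pick g so total time = L / v_avg
    dt_unit = seg_len * seg_kappa**beta
    duration = path.total_length / average_speed
    gain = dt_unit.sum() / duration
    t_cum = np.concatenate([[0.0], np.cumsum(dt_unit / gain)])
    t_frames = _frame_times(duration, frame_rate)
    s = np.interp(t_frames, t_cum, path.arc_length)
    return s / path.total_length


# ---------------------------------------------------------------------------
# Trajectories and the default battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """A path with a 60 Hz time parameterization.

    ``frames`` holds the target center position per display frame;
    ``frame_angles`` the analytic target tangential angle at each frame
    (interpolated from the path construction, not re-estimated from the
    rendered positions).
    """

    path: Path
    frames: np.ndarray
    frame_angles: np.ndarray
    duration: float
    label: str
    average_speed: float
    frame_rate: float = DEFAULT_FRAME_RATE

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def build_trajectory(
    spec: PathSpec,
    profile_family: str,
    average_speed: float,
    label: str,
    beta: float = 1.0 / 3.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    center_on_screen: bool = True,
) -> Trajectory:
    """Build one labeled trajectory from a path spec and a motion profile."""
    if profile_family not in _PROFILE_FAMILIES:
        raise ConfigError(
            f"unknown profile_family {profile_family!r}; expected one of "
            f"{_PROFILE_FAMILIES}"
        )
    path = path_from_angles(build_angle_array(spec), spec.step)
    if center_on_screen:
        lo = path.points.min(axis=0)
        hi = path.points.max(axis=0)
        shift = np.array(SCREEN_PX, dtype=float) / 2.0 - (lo + hi) / 2.0
        path = Path(
            points=path.points + shift,
            tangent_angle=path.tangent_angle,
            curvature=path.curvature,
            arc_length=path.arc_length,
        )
    length = path.total_length
    if profile_family == "minimum_jerk":
        frac = minimum_jerk_timing(length, average_speed, frame_rate)
    elif profile_family == "constant_speed":
        frac = constant_speed_timing(length, average_speed, frame_rate)
    else:
        frac = power_law_timing(path, average_speed, beta, frame_rate)
    s = frac * length
    frames = np.column_stack(
        [
            np.interp(s, path.arc_length, path.points[:, 0]),
            np.interp(s, path.arc_length, path.points[:, 1]),
        ]
    )
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(path.tangent_angle)))
    frame_angles = wrap_angle_deg(np.interp(s, path.arc_length, unwrapped))
    return Trajectory(
        path=path,
        frames=frames,
        frame_angles=frame_angles,
        duration=length / average_speed,
        label=label,
        average_speed=average_speed,
        frame_rate=frame_rate,
    )


_REQUIRED_TRAJ_KEYS = {"family", "extent_px", "speed_px_s", "profile"}


def default_battery_config() -> dict:
    """Load the battery configuration shipped with the package."""
    text = resources.files("pursuitkit").joinpath("data/battery.yaml").read_text()
    return yaml.safe_load(text)


def load_battery_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def battery_config_hash(config: Mapping) -> str:
    """Stable short hash of a battery configuration."""
    canon = json.dumps(config, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_battery(config: Mapping | None = None) -> dict[str, Trajectory]:
    """Build the full stimulus battery (nine labeled trajectories by default).

    Line trajectories use minimum-jerk (hline) or constant-speed timing
    (tilted lines); zigzags and spirals use the speed–curvature power
    law.  With the shipped configuration the trajectory durations equal
    extent / speed, e.g. hline 427 px / 100 px/s = 4.27 s.
    """
    if config is None:
        config = default_battery_config()
    try:
        traj_cfgs = config["trajectories"]
    except (KeyError, TypeError):
        raise ConfigError("battery config missing 'trajectories' section")
    frame_rate = float(config.get("frame_rate", DEFAULT_FRAME_RATE))
    battery: dict[str, Trajectory] = {}
    for label, cfg in traj_cfgs.items():
        missing = _REQUIRED_TRAJ_KEYS - set(cfg)
        if missing:
            raise ConfigError(f"trajectory {label!r} missing keys: {sorted(missing)}")
        family = cfg["family"]
        shaping = {
            key: float(val)
            for key, val in cfg.items()
            if key
            not in _REQUIRED_TRAJ_KEYS | {"beta", "step_px"}
        }
        spec = PathSpec(
            shape_family=family,
            extent=float(cfg["extent_px"]),
            step=float(cfg.get("step_px", 1.0)),
            shaping=shaping,
        )
        battery[label] = build_trajectory(
            spec,
            profile_family=cfg["profile"],
            average_speed=float(cfg["speed_px_s"]),
            label=label,
            beta=float(cfg.get("beta", 1.0 / 3.0)),
            frame_rate=frame_rate,
        )
    return battery
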