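"""Synthetic participants and cohorts.

The pursuit model is a first-order lagged tracker: at each frame the
simulated fingertip closes a fixed fraction (``gain``) of its distance
to where the target was ``lag_s`` seconds ago, plus isotropic process
noise and an optional low-amplitude tremor oscillation.  It is a
fixture generator with tunable, age-linked difficulty — not a claim
about child motor control — but it produces the qualitative structure
the analysis layer assumes: nonzero directional *and* spatial offsets
that shrink as lag and noise shrink.

Cohorts mirror a small repeated-measures study: each participant gets
an age, participant-level random intercepts on the pursuit parameters
and on the external score, up to four sessions advancing in age, and
an external motor score generated as a linear function of the realized
mean directional offsets of the two slowest complex trajectories
(spiralA, zigzagA) plus the participant intercept and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from pursuitkit.acquisition import (
    SessionRecord,
    TouchTrace,
    detect_resets,
    write_session,
)
from pursuitkit.metrics import score_session
from pursuitkit.stimulus import PIXEL_PITCH_MM, Trajectory, build_battery


class SpecError(ValueError):
    """Raised for infeasible simulation specifications."""


@dataclass(frozen=True)
class PursuitParams:
    """Behavioral parameters of one simulated tracker."""

    lag_s: float = 0.30
    gain: float = 0.18
    noise_sd_mm: float = 0.8
    tremor_amp_mm: float = 0.0
    tremor_hz: float = 5.0
    lift_prob: float = 0.0
    lift_mean_frames: float = 6.0
    #: reference target speed (px/s) at which noise_sd_mm applies; the
    #: effective noise scales with local target speed (signal-dependent
    #: motor noise), so directional error is a speed-invariant trait
    noise_ref_speed_px_s: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.lag_s < 0:
            raise SpecError(f"lag_s must be >= 0, got {self.lag_s}")
        if not 0 < self.gain <= 1:
            raise SpecError(f"gain must be in (0, 1], got {self.gain}")
        if self.noise_sd_mm < 0:
            raise SpecError(f"noise_sd_mm must be >= 0, got {self.noise_sd_mm}")
        if not 0 <= self.lift_prob <= 1:
            raise SpecError(f"lift_prob must be in [0, 1], got {self.lift_prob}")


def simulate_touch(
    traj: Trajectory,
    params: PursuitParams,
    rng: np.random.Generator | None = None,
) -> TouchTrace:
    """Simulate one touch trace tracking one trajectory.

    ``touch[i] = touch[i-1] + gain * (target(t_i - lag) - touch[i-1])
    + noise`` — a linear recursion evaluated with an IIR filter — with
    tremor added on top and optional brief touch drops.  Deterministic
    for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = traj.n_frames
    fr = traj.frame_rate
    shift = int(round(params.lag_s * fr))
    if shift >= n:
        raise SpecError(
            f"lag {params.lag_s} s >= trajectory duration "
            f"{n / fr:.2f} s ({traj.label})"
        )
    delayed = traj.frames[np.maximum(np.arange(n) - shift, 0)]
    g = params.gain
    # signal-dependent noise: SD proportional to local target speed
    # (noise_sd_mm is calibrated at noise_ref_speed_px_s)
    seg_speed = np.hypot(*np.gradient(delayed, axis=0).T) * fr
    scale = np.clip(seg_speed / params.noise_ref_speed_px_s, 0.25, 4.0)
    noise_px = rng.normal(0.0, params.noise_sd_mm / PIXEL_PITCH_MM, size=(n, 2))
    noise_px *= scale[:, None]
    drive = g * delayed + noise_px
    drive[0] = traj.frames[0]  # finger starts on the target
    b, a = [1.0], [1.0, -(1.0 - g)]
    touch = np.empty((n, 2))
    for axis in range(2):
        zi = np.atleast_1d((1.0 - g) * traj.frames[0, axis])
        touch[:, axis], _ = sp_signal.lfilter(b, a, drive[:, axis], zi=zi)
    if params.tremor_amp_mm > 0:
        t = np.arange(n) / fr
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp_px = params.tremor_amp_mm / PIXEL_PITCH_MM
        touch[:, 0] += amp_px * np.sin(2 * np.pi * params.tremor_hz * t + phase[0])
        touch[:, 1] += amp_px * np.sin(2 * np.pi * params.tremor_hz * t + phase[1])
    active = np.ones(n, dtype=bool)
    if params.lift_prob > 0:
        starts = rng.random(n) < params.lift_prob
        durations = rng.geometric(1.0 / params.lift_mean_frames, size=n)
        for i in np.flatnonzero(starts):
            active[i : i + durations[i]] = False
    return TouchTrace(
        t_ms=np.arange(n) * 1000.0 / fr,
        touch=touch,
        active=active,
        trajectory_label=traj.label,
        frame_rate=fr,
        target=traj.frames,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default age -> pursuit-parameter maps: value = intercept + b1*age + b2*age^2,
#: clipped into [lo, hi].  Lag and noise fall with age (motor maturation).
DEFAULT_AGE_MODELS: dict[str, dict[str, float]] = {
    # lag falls steeply with age: spatial offset scales with speed * lag,
    # giving the strong age dependence of the spatial metric
    "lag_s": {"intercept": 0.70, "age": -0.050, "age2": 0.0015, "lo": 0.06, "hi": 1.0},
    # process noise (which mostly disturbs movement *direction*) falls
    # only mildly with age
    "noise_sd_mm": {"intercept": 1.7, "age": -0.07, "age2": 0.0, "lo": 0.15, "hi": 5.0},
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative design of a synthetic cohort.

    Defaults mirror a small clinical repeated-measures design: 12
    participants aged 5–16, up to 4 sessions each, participant random
    intercepts, and an external motor score (on a VMI-MC-like points
    scale) driven by the directional offsets of spiralA and zigzagA.
    """

    n_participants: int = 12
    sessions_per_participant: int = 4
    age_range_years: tuple[float, float] = (5.0, 16.0)
    session_age_step_years: float = 0.25
    age_models: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_AGE_MODELS
    )
    gain: float = 0.18
    tremor_amp_mm: float = 0.3
    tremor_hz: float = 5.0
    lift_prob: float = 0.002
    lag_intercept_sd: float = 0.04
    noise_intercept_sd: float = 0.40
    score_intercept: float = 34.0
    score_weight_spiralA: float = -0.25
    score_weight_zigzagA: float = -0.12
    score_intercept_sd: float = 1.5
    score_residual_sd: float = 1.0
    skip_prob: float = 0.0
    skip_labels: tuple[str, ...] = ("zigzagC", "spiralC")
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise SpecError("need at least 2 participants")
        if not self.score_residual_sd > 0:
            raise SpecError("score residual SD must be > 0")
        for name, sd in (
            ("lag_intercept_sd", self.lag_intercept_sd),
            ("noise_intercept_sd", self.noise_intercept_sd),
            ("score_intercept_sd", self.score_intercept_sd),
        ):
            if sd < 0:
                raise SpecError(f"{name} must be >= 0")
        lo, hi = self.age_range_years
        if not lo < hi:
            raise SpecError("age_range_years must be (lo, hi) with lo < hi")
        for pname, model in self.age_models.items():
            probe = [
                _age_model_value(model, age) for age in np.linspace(lo, hi, 23)
            ]
            if min(probe) < 0:
                raise SpecError(
                    f"age model for {pname!r} goes negative within the age range"
                )


def _age_model_value(model: Mapping[str, float], age: float) -> float:
    raw = (
        model.get("intercept", 0.0)
        + model.get("age", 0.0) * age
        + model.get("age2", 0.0) * age * age
    )
    return float(np.clip(raw, model.get("lo", 0.0), model.get("hi", np.inf)))


def participant_params(
    spec: CohortSpec, age: float, lag_u: float = 0.0, noise_u: float = 0.0
) -> PursuitParams:
    """Pursuit parameters for a participant of a given age."""
    lag = _age_model_value(spec.age_models["lag_s"], age) + lag_u
    noise = _age_model_value(spec.age_models["noise_sd_mm"], age) + noise_u
    return PursuitParams(
        lag_s=float(np.clip(lag, 0.02, 1.5)),
        gain=spec.gain,
        noise_sd_mm=float(np.clip(noise, 0.05, 8.0)),
        tremor_amp_mm=spec.tremor_amp_mm,
        tremor_hz=spec.tremor_hz,
        lift_prob=spec.lift_prob,
    )


SCORE_LABELS = ("spiralA", "zigzagA")


def simulate_cohort(
    spec: CohortSpec,
    battery: dict[str, Trajectory] | None = None,
    labels: Sequence[str] | None = None,
    out_dir=None,
    record_resets: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, score and (optionally) persist a whole cohort.

    Returns ``(cohort, truth)``: the scored cohort table (one row per
    participant-session with per-trajectory mean offsets and the
    generated external score) and a truth table with the generative
    parameters for parameter-recovery studies.  With ``out_dir`` set,
    session directories in the acquisition format plus ``cohort.csv``
    and ``truth.csv`` are written.

    ``labels`` restricts simulation to a battery subset; the score
    trajectories (spiralA, zigzagA) are always included.
    """
    rng = np.random.default_rng(spec.seed)
    if battery is None:
        battery = build_battery()
    if labels is None:
        labels = list(battery)
    labels = list(dict.fromkeys(list(labels) + list(SCORE_LABELS)))
    missing = [lab for lab in labels if lab not in battery]
    if missing:
        raise SpecError(f"labels not in battery: {missing}")

    lo, hi = spec.age_range_years
    base_ages = rng.uniform(lo, hi, size=spec.n_participants)
    lag_us = rng.normal(0.0, spec.lag_intercept_sd, size=spec.n_participants)
    noise_us = rng.normal(0.0, spec.noise_intercept_sd, size=spec.n_participants)
    score_us = rng.normal(0.0, spec.score_intercept_sd, size=spec.n_participants)

    cohort_rows = []
    truth_rows = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        for s in range(1, spec.sessions_per_participant + 1):
            age = base_ages[p] + spec.session_age_step_years * (s - 1)
            params = participant_params(spec, age, lag_us[p], noise_us[p])
            record = SessionRecord(
                participant_id=pid, session_index=s, age_years=float(age)
            )
            for label in labels:
                if (
                    label in spec.skip_labels
                    and label not in SCORE_LABELS
                    and rng.random() < spec.skip_prob
                ):
                    continue
                record.traces[label] = simulate_touch(battery[label], params, rng)
            if record_resets:
                for label, trace in record.traces.items():
                    record.resets.extend(detect_resets(trace, battery[label]))
            summaries = score_session(
                record, battery, detect_reset_events=record_resets
            )
            row = {
                "participant_id": pid,
                "session_index": s,
                "age_years": float(age),
            }
            for label, summ in summaries.items():
                if summ is None:
                    continue
                row[f"dir_{label}"] = summ.mean_directional_offset_deg
                row[f"spa_{label}"] = summ.mean_spatial_offset_mm
            score = (
                spec.score_intercept
                + spec.score_weight_spiralA * row["dir_spiralA"]
                + spec.score_weight_zigzagA * row["dir_zigzagA"]
                + score_us[p]
                + rng.normal(0.0, spec.score_residual_sd)
            )
            row["external_score"] = float(score)
            cohort_rows.append(row)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "session_index": s,
                    "age_years": float(age),
                    "lag_s": params.lag_s,
                    "gain": params.gain,
                    "noise_sd_mm": params.noise_sd_mm,
                    "score_intercept_u": score_us[p],
                }
            )
            if out_dir is not None:
                write_session(record, FilePath(out_dir) / pid / f"session{s:02d}")
    cohort = pd.DataFrame(cohort_rows)
    truth = pd.DataFrame(truth_rows)
    cohort["age_sq"] = cohort["age_years"] ** 2
    if out_dir is not None:
        out = FilePath(out_dir)
        cohort.to_csv(out / "cohort.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return cohort, truth
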