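import numpy as np
import pytest

from pursuitkit.acquisition import TouchTrace
from pursuitkit.stimulus import build_battery


@pytest.fixture(scope="session")
def battery():
    """Default nine-trajectory battery, built once per test session."""
    return build_battery()


@pytest.fixture(scope="session")
def score_battery(battery):
    """The two score-model trajectories only (fast cohort simulations)."""
    return {k: battery[k] for k in ("spiralA", "zigzagA")}


def make_trace(traj, offset_px=(0.0, 0.0), active=None, jitter_ms=0.0, rng=None):
    """A touch trace that shadows the target at a fixed pixel offset."""
    n = traj.n_frames
    t_ms = np.arange(n) * 1000.0 / traj.frame_rate
    if jitter_ms:
        rng = rng or np.random.default_rng(0)
        t_ms = t_ms + rng.normal(0.0, jitter_ms, size=n)
        t_ms = np.sort(t_ms)
    touch = traj.frames + np.asarray(offset_px, dtype=float)
    if active is None:
        active = np.ones(n, dtype=bool)
    return TouchTrace(
        t_ms=t_ms,
        touch=touch,
        active=active,
        trajectory_label=traj.label,
        frame_rate=traj.frame_rate,
        target=traj.frames,
    )
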