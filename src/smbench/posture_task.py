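"""Virtual posture-matching task: closed-loop trials and outcome metrics.

The virtual hand has 4 normalized joint angles in [-1, 1].  Each trial
presents a pseudo-random 4-DOF target posture; the (synthetic) user emits
WFL frames at 20 Hz, the controller converts them to joint velocities, and
the hand integrates.  A trial succeeds when all four angles stay within
15% of each DOF's full range (0.15 x 2.0 = 0.3 normalized units) of the
target continuously for 1 s within the 30 s limit.

Outcomes mirror the standard target-acquisition metrics: match percentage,
time-to-target (entry time of the successful hold window), and path
efficiency (straight-line / traveled joint-space distance up to the
match), with unmatched trials excluded from the latter two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ann_controller import ControllerSpec, integrate_hand, predict_velocity

__all__ = [
    "TOLERANCE",
    "HOLD_S",
    "TRIAL_LIMIT_S",
    "TargetPosture",
    "TrialResult",
    "TaskSummary",
    "generate_targets",
    "run_trial",
    "path_efficiency",
    "within_tolerance",
    "summarize_task",
]

FRAME_RATE = 20
DT = 1.0 / FRAME_RATE
#: 15% of each DOF's full range ([-1, 1] -> range 2.0).
TOLERANCE = 0.15 * 2.0
HOLD_S = 1.0
HOLD_FRAMES = int(round(HOLD_S * FRAME_RATE))
TRIAL_LIMIT_S = 30.0


@dataclass(frozen=True)
class TargetPosture:
    """One pseudo-random 4-DOF target, guaranteed non-trivial at start."""

    angles: np.ndarray
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if self.angles.shape != (4,):
            raise ValueError("target must have 4 joint angles")
        if np.any(np.abs(self.angles) > 1):
            raise ValueError("target angles must lie in [-1, 1]")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one posture-matching trial."""

    matched: bool
    time_to_target: float | None
    path_efficiency: float | None
    trajectory: np.ndarray          # frames x 4, state after each update
    target: np.ndarray

    def __post_init__(self):
        if self.matched:
            if self.time_to_target is None or self.time_to_target > TRIAL_LIMIT_S:
                raise ValueError("matched trial needs time_to_target <= limit")
        else:
            if self.time_to_target is not None or self.path_efficiency is not None:
                raise ValueError("unmatched trial carries no outcome metrics")


def within_tolerance(state: np.ndarray, target: np.ndarray, tol: float = TOLERANCE) -> bool:
    """All four joints within the per-DOF tolerance of the target."""
    return bool(np.all(np.abs(np.asarray(state) - np.asarray(target)) <= tol))


def generate_targets(
    n: int = 80,
    seed: int = 0,
    start: np.ndarray | None = None,
    tol: float = TOLERANCE,
) -> list[TargetPosture]:
    """Draw n targets uniformly over [-1, 1]^4, rejecting any already
    satisfied at the start state (every DOF within tolerance)."""
    rng = np.random.default_rng(seed)
    start = np.zeros(4) if start is None else np.asarray(start, dtype=float)
    targets: list[TargetPosture] = []
    while len(targets) < n:
        cand = rng.uniform(-1.0, 1.0, size=4)
        if within_tolerance(start, cand, tol):
            continue
        targets.append(TargetPosture(angles=cand, seed=seed))
    return targets


def path_efficiency(trajectory: np.ndarray, start: np.ndarray | None = None) -> float:
    """Straight-line over traveled joint-space distance for a trajectory.

    ``trajectory`` rows are successive 4-DOF states, the last being the
    matched posture.  An out-and-back path with zero net displacement is
    degenerate and returns 0.0.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 points")
    if start is not None:
        traj = np.vstack([np.asarray(start, dtype=float), traj])
    traveled = float(np.linalg.norm(np.diff(traj, axis=0), axis=1).sum())
    if traveled <= 0:
        raise ValueError("total traveled distance must be positive")
    straight = float(np.linalg.norm(traj[-1] - traj[0]))
    return straight / traveled


def run_trial(
    spec: ControllerSpec,
    user: Callable[[np.ndarray, np.ndarray], np.ndarray],
    target: TargetPosture,
    *,
    start: np.ndarray | None = None,
    trial_limit_s: float = TRIAL_LIMIT_S,
    tol: float = TOLERANCE,
) -> TrialResult:
    """Run one closed-loop posture-matching trial at 20 Hz.

    ``user(state, target_angles)`` returns the next WFL frame.  Success
    requires ``HOLD_FRAMES`` consecutive in-tolerance frames within the
    trial limit; time_to_target is the entry time of that hold window and
    path efficiency is computed over the trajectory up to the hold entry.
    """
    start = np.zeros(4) if start is None else np.asarray(start, dtype=float)
    state = start.copy()
    n_frames = int(round(trial_limit_s / DT))
    traj = [state.copy()]
    hold = 0
    hold_entry_frame: int | None = None
    for frame in range(1, n_frames + 1):
        wfl = user(state, target.angles)
        vel = predict_velocity(spec, wfl)
        state = integrate_hand(state, vel, DT)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("non-finite hand state during trial")
        traj.append(state.copy())
        if within_tolerance(state, target.angles, tol):
            if hold == 0:
                hold_entry_frame = frame
            hold += 1
            if hold >= HOLD_FRAMES:
                t_match = hold_entry_frame * DT
                upto = np.asarray(traj[: hold_entry_frame + 1])
                try:
                    eff = path_efficiency(upto)
                except ValueError:
                    eff = 0.0  # degenerate: matched without net movement
                return TrialResult(
                    matched=True,
                    time_to_target=t_match,
                    path_efficiency=eff,
                    trajectory=np.asarray(traj),
                    target=target.angles,
                )
        else:
            hold = 0
            hold_entry_frame = None
    return TrialResult(
        matched=False,
        time_to_target=None,
        path_efficiency=None,
        trajectory=np.asarray(traj),
        target=target.angles,
    )


@dataclass(frozen=True)
class TaskSummary:
    """Aggregate posture-task outcomes for one controller."""

    n_trials: int
    n_matched: int
    match_pct: float
    time_to_target_mean: float | None
    time_to_target_se: float
    path_efficiency_mean: float | None
    path_efficiency_se: float
    per_posture: dict[int, dict[str, float]] = field(default_factory=dict)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return mean, se


def summarize_task(
    results: Sequence[TrialResult],
    posture_index: Sequence[int] | None = None,
) -> TaskSummary:
    """Match %, and per-posture session-mean time/efficiency (mean +/- SE).

    ``posture_index[i]`` identifies the target posture of ``results[i]``
    across sessions; trials of the same posture are averaged first
    (unsuccessful trials excluded), then mean +/- SE is taken across
    postures.  Without an index every trial counts as its own posture.
    """
    n = len(results)
    if posture_index is None:
        posture_index = list(range(n))
    if len(posture_index) != n:
        raise ValueError("posture_index must align with results")
    n_matched = sum(r.matched for r in results)
    per_posture: dict[int, dict[str, list[float]]] = {}
    for idx, r in zip(posture_index, results):
        if not r.matched:
            continue
        slot = per_posture.setdefault(int(idx), {"time": [], "eff": []})
        slot["time"].append(r.time_to_target)
        slot["eff"].append(r.path_efficiency)
    posture_means = {
        idx: {
            "time_to_target": float(np.mean(v["time"])),
            "path_efficiency": float(np.mean(v["eff"])),
        }
        for idx, v in per_posture.items()
    }
    if posture_means:
        times = np.array([v["time_to_target"] for v in posture_means.values()])
        effs = np.array([v["path_efficiency"] for v in posture_means.values()])
        t_mean, t_se = _mean_se(times)
        e_mean, e_se = _mean_se(effs)
    else:
        t_mean = e_mean = None
        t_se = e_se = 0.0
    return TaskSummary(
        n_trials=n,
        n_matched=n_matched,
        match_pct=100.0 * n_matched / n if n else 0.0,
        time_to_target_mean=t_mean,
        time_to_target_se=t_se,
        path_efficiency_mean=e_mean,
        path_efficiency_se=e_se,
        per_posture=posture_means,
    )
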