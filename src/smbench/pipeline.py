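"""End-to-end convenience flows shared by the analysis drivers and tests.

These functions chain the module-level operations in the order the
analyses use them: synthetic EMG -> hygiene (outlier repetition and dead
channel handling) -> training set -> trained controller -> closed-loop
posture-matching session; and electrode model -> percept sessions ->
coverage / cluster summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ann_controller import AnnModel, ControllerSpec, train_ann
from .emg_features import (
    CHANNEL_SUBSETS,
    EmgTrial,
    build_training_set,
    detect_nonresponsive_channels,
    exclude_outlier_repetition,
)
from .percept_clustering import ClusterCurve, cluster_curve
from .percept_maps import HandTemplate, cumulative_coverage
from .posture_task import TrialResult, generate_targets, run_trial, summarize_task
from .synthetic_data import (
    ElectrodeModel,
    SynergyModel,
    SyntheticUser,
    generate_emg_dataset,
    generate_percept_sessions,
)

__all__ = [
    "prepare_training_trials",
    "train_controller",
    "run_posture_sessions",
    "percept_summaries",
]


def prepare_training_trials(
    model: SynergyModel, seed: int = 0, reps: int = 10
) -> list[EmgTrial]:
    """Generate the prompted-posture dataset and drop the least-similar
    repetition of each posture (10 reps collected -> 9 retained)."""
    trials = generate_emg_dataset(model, reps=reps, seed=seed)
    by_posture: dict[tuple, list[EmgTrial]] = {}
    for t in trials:
        by_posture.setdefault(t.posture, []).append(t)
    kept: list[EmgTrial] = []
    for posture_reps in by_posture.values():
        kept.extend(exclude_outlier_repetition(posture_reps))
    return kept


def train_controller(
    trials: Sequence[EmgTrial],
    subset: str | Sequence[int],
    seed: int = 0,
    *,
    gains: float = 1.0,
    thresholds: float = 0.1,
) -> tuple[ControllerSpec, AnnModel]:
    """Build the training set for a channel subset and train its controller."""
    channels = CHANNEL_SUBSETS[subset] if isinstance(subset, str) else tuple(subset)
    ts = build_training_set(trials, channels, seed=seed)
    model = train_ann(ts, seed=seed)
    spec = ControllerSpec(
        channel_ids=channels,
        model=model,
        gains=np.full(4, gains),
        thresholds=np.full(4, thresholds),
    )
    return spec, model


def run_posture_sessions(
    spec: ControllerSpec,
    synergy: SynergyModel,
    *,
    n_sessions: int = 1,
    n_targets: int = 80,
    seed: int = 0,
    user_noise: float = 0.1,
) -> tuple[list[TrialResult], list[int]]:
    """Run closed-loop posture-matching sessions with the synthetic user.

    Targets are regenerated per session; returns all trial results plus the
    per-trial target index (shared across sessions) for per-posture
    averaging.
    """
    results: list[TrialResult] = []
    posture_index: list[int] = []
    for s in range(n_sessions):
        user = SyntheticUser(
            synergy, channels=spec.channel_ids, noise=user_noise,
            seed=seed * 1000 + s,
        )
        targets = generate_targets(n=n_targets, seed=seed * 1000 + 500 + s)
        for i, target in enumerate(targets):
            results.append(run_trial(spec, user, target))
            posture_index.append(i)
    return results, posture_index


@dataclass(frozen=True)
class PerceptSummary:
    coverage: list[float]
    curves: list[ClusterCurve]

    def mean_coverage(self) -> float:
        return float(np.mean(self.coverage))

    def mean_count(self, cutoff: float) -> float:
        return float(np.mean([c.count_at(cutoff) for c in self.curves]))


def percept_summaries(
    model: ElectrodeModel,
    template: HandTemplate,
    *,
    n_sessions: int = 3,
    seed: int = 0,
    system_id: str = "system",
) -> PerceptSummary:
    """Coverage and unique-percept cluster curves over simulated sessions."""
    sessions = generate_percept_sessions(
        model, template, n_sessions, seed=seed, system_id=system_id
    )
    coverage = [cumulative_coverage(s.drawings, template) for s in sessions]
    curves = [
        cluster_curve(
            s.drawings, system_id=system_id, session_id=s.session_id
        )
        for s in sessions
    ]
    return PerceptSummary(coverage=coverage, curves=curves)
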