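"""Group comparisons for controller outcomes.

Match percentages between controllers are compared with two-sided Fisher's
exact tests on matched/unmatched counts; per-posture time-to-target and
path-efficiency means are compared with one-way ANOVA plus Tukey's HSD
post-hoc pairwise adjustment at alpha = 0.05.  Summaries are reported as
mean +/- standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ALPHA",
    "ContingencyTable2x2",
    "fisher_exact",
    "anova_tukey",
    "mean_se",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Matched/unmatched counts for two controllers."""

    matched_a: int
    unmatched_a: int
    matched_b: int
    unmatched_b: int

    def __post_init__(self):
        cells = (self.matched_a, self.unmatched_a, self.matched_b, self.unmatched_b)
        if any(c < 0 or int(c) != c for c in cells):
            raise ValueError("cell counts must be non-negative integers")
        if self.matched_a + self.unmatched_a == 0 or self.matched_b + self.unmatched_b == 0:
            raise ValueError("both controllers need at least one trial")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.matched_a, self.unmatched_a], [self.matched_b, self.unmatched_b]],
            dtype=int,
        )


def fisher_exact(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher's exact p-value (probability-mass rule).

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed
    table's — the common toolbox definition of "two-sided".
    """
    arr = table.table if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def anova_tukey(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> dict:
    """One-way ANOVA with Tukey HSD pairwise post-hoc comparisons.

    ``groups`` maps controller names to per-posture outcome values
    (unbalanced group sizes are accepted).  Returns ``{"F", "p",
    "pairwise": {(a, b): adjusted p}, "significant": {(a, b): bool}}``
    with significance at alpha = 0.05.
    """
    if isinstance(groups, Mapping):
        names = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in data):
        raise ValueError("every group needs at least 2 values")
    F, p = stats.f_oneway(*data)
    if not np.isfinite(F):  # all groups identical and constant
        F, p = 0.0, 1.0
    res = stats.tukey_hsd(*data)
    pairwise = {}
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            pairwise[(names[i], names[j])] = float(res.pvalue[i, j])
    return {
        "F": float(F),
        "p": float(p),
        "pairwise": pairwise,
        "significant": {k: v < ALPHA for k, v in pairwise.items()},
    }


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error (SD / sqrt(n)); n = 1 gives SE 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_se of empty sequence")
    if arr.size == 1:
        warnings.warn("single value: SE reported as 0", RuntimeWarning, stacklevel=2)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
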