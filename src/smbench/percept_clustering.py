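"""Unique-percept-location model: Jaccard dissimilarity + complete linkage.

The number of "unique" percept locations a stimulation system can evoke is
estimated by (1) computing the pairwise location dissimilarity

    D = 1 - |L1 n L2| / |L1 u L2|

between binary percept masks (0 = identical, 1 = non-overlapping), (2)
building a complete-linkage hierarchy over the non-painful percepts of a
session, and (3) cutting the dendrogram at a dissimilarity cutoff swept
over 0.01..1.00; the cluster count at each cutoff estimates the number of
unique percept locations.

The agglomerator is implemented here with an explicit, platform-stable
tie-break (lexicographically smallest label pair merges first) so cluster
counts are reproducible; tests cross-check its merge heights against
scipy's complete-linkage implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .percept_maps import PerceptDrawing

__all__ = [
    "DissimilarityMatrix",
    "LinkageTree",
    "ClusterCurve",
    "DEFAULT_CUTOFF_GRID",
    "location_dissimilarity",
    "nonpainful_predicate",
    "build_dissimilarity_matrix",
    "complete_linkage",
    "cluster_count",
    "cluster_labels",
    "cluster_curve",
    "summarize_sessions",
]

#: Dissimilarity cutoffs 0.01..1.00 in increments of 0.01.
DEFAULT_CUTOFF_GRID = np.round(np.arange(1, 101) * 0.01, 2)


def location_dissimilarity(L1: np.ndarray, L2: np.ndarray) -> float:
    """Complement of the Jaccard similarity between two binary masks.

    Returns 0 for identical masks, 1 for non-overlapping masks.  Raises if
    the masks are not congruent or both are empty (the quantity is
    undefined; only evoked percepts are clustered).
    """
    L1 = np.asarray(L1, dtype=bool)
    L2 = np.asarray(L2, dtype=bool)
    if L1.shape != L2.shape:
        raise ValueError(f"mask shapes differ: {L1.shape} vs {L2.shape}")
    union = int(np.logical_or(L1, L2).sum())
    if union == 0:
        raise ValueError("both masks empty: dissimilarity undefined")
    inter = int(np.logical_and(L1, L2).sum())
    return 1.0 - inter / union


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise location-dissimilarity matrix with contact labels."""

    labels: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError(f"matrix shape {D.shape} does not match {n} labels")
        if not np.all(np.isfinite(D)):
            raise ValueError("dissimilarity matrix contains non-finite entries")
        if not np.allclose(D, D.T):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("dissimilarity matrix diagonal must be zero")
        if D.min() < -1e-12 or D.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class LinkageTree:
    """Complete-linkage merge list over n leaves.

    ``merges[k] = (a, b, height, size)`` joins clusters ``a`` and ``b``
    (indices < n are leaves; index n+k is the cluster formed by merge k)
    at the given dissimilarity height.  Complete linkage guarantees the
    heights are non-decreasing.
    """

    n: int
    merges: tuple[tuple[int, int, float, int], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "merges", tuple(map(tuple, self.merges)))
        if len(self.merges) != self.n - 1:
            raise ValueError(f"expected {self.n - 1} merges, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(h2 + 1e-12 < h1 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges], dtype=float)


@dataclass(frozen=True)
class ClusterCurve:
    """Cluster count as a function of dissimilarity cutoff for one session."""

    cutoffs: np.ndarray
    counts: np.ndarray
    system_id: str = ""
    session_id: str = ""
    subset: str = "all"

    def __post_init__(self):
        object.__setattr__(self, "cutoffs", np.asarray(self.cutoffs, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if self.cutoffs.shape != self.counts.shape:
            raise ValueError("cutoffs and counts must align")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("cluster counts must be non-increasing in cutoff")

    def count_at(self, cutoff: float) -> int:
        idx = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        if abs(self.cutoffs[idx] - cutoff) > 1e-9:
            raise KeyError(f"cutoff {cutoff} not on the grid")
        return int(self.counts[idx])


def nonpainful_predicate(d: PerceptDrawing) -> bool:
    """Default inclusion rule: tactile and/or proprioceptive, not painful."""
    return (
        ("tactile" in d.categories or "proprioceptive" in d.categories)
        and "painful" not in d.categories
    )


def build_dissimilarity_matrix(
    drawings: Sequence[PerceptDrawing],
    include: Callable[[PerceptDrawing], bool] | None = nonpainful_predicate,
) -> DissimilarityMatrix:
    """Pairwise dissimilarity matrix over the drawings passing ``include``.

    Drawings with empty masks (e.g. fully clipped at the wrist) are dropped
    since the dissimilarity is undefined for them.  Requires at least two
    survivors.
    """
    if include is None:
        include = lambda d: True
    kept = [d for d in drawings if include(d) and d.mask.any()]
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 nonempty drawings after filtering, got {len(kept)} "
            f"(filter {getattr(include, '__name__', repr(include))})"
        )
    n = len(kept)
    flat = np.stack([d.mask.ravel() for d in kept]).astype(np.float64)
    inter = flat @ flat.T  # pairwise intersection pixel counts
    areas = flat.sum(axis=1)
    union = areas[:, None] + areas[None, :] - inter
    D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(
        labels=tuple(d.contact_id for d in kept), D=np.asarray(D, dtype=float)
    )


def complete_linkage(Dm: DissimilarityMatrix) -> LinkageTree:
    """Agglomerative complete-linkage hierarchy of a dissimilarity matrix.

    Inter-cluster distance is the maximum pairwise dissimilarity.  Among
    equal-height candidate merges the lexicographically smallest cluster
    index pair merges first, making the tree deterministic.
    """
    n = Dm.n
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    # active cluster id -> set of leaves; working distance dict
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = Dm.D[i, j]
    members = {i: [i] for i in range(n)}
    sizes = dict.fromkeys(range(n), 1)
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        size = sizes[a] + sizes[b]
        merges.append((a, b, float(h), size))
        members[next_id] = members.pop(a) + members.pop(b)
        sizes[next_id] = size
        del sizes[a], sizes[b]
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c in sizes:
            if c == next_id:
                continue
            d_new = max(
                Dm.D[i, j] for i in members[c] for j in members[next_id]
            )
            dist[(min(c, next_id), max(c, next_id))] = d_new
        next_id += 1
    return LinkageTree(n=n, merges=tuple(merges), labels=Dm.labels)


def cluster_labels(tree: LinkageTree, cutoff: float) -> np.ndarray:
    """Leaf -> cluster-id assignment after cutting merges above ``cutoff``.

    Inclusive semantics: a merge at exactly the cutoff height is kept
    (percepts at D == cutoff count as the same percept).
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    parent = list(range(2 * tree.n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h, _) in enumerate(tree.merges):
        if h <= cutoff + 1e-12:
            node = tree.n + k
            parent[find(a)] = node
            parent[find(b)] = node
    roots = {}
    out = np.empty(tree.n, dtype=int)
    for leaf in range(tree.n):
        r = find(leaf)
        out[leaf] = roots.setdefault(r, len(roots))
    return out


def cluster_count(tree: LinkageTree, cutoff: float) -> int:
    """Number of unique-percept clusters after cutting at ``cutoff``."""
    return int(cluster_labels(tree, cutoff).max()) + 1


def cluster_curve(
    drawings: Sequence[PerceptDrawing],
    include: Callable[[PerceptDrawing], bool] | None = nonpainful_predicate,
    cutoffs: np.ndarray = DEFAULT_CUTOFF_GRID,
    *,
    system_id: str = "",
    session_id: str = "",
    subset: str = "all",
) -> ClusterCurve:
    """Cluster count vs. dissimilarity cutoff for one session's drawings.

    ``include`` composes the category rule with any subset selection (by
    nerve or electrode) needed for per-interface comparisons.  A subset
    with a single surviving percept yields a curve constant at 1.
    """
    if include is None:
        include = lambda d: True
    kept = [d for d in drawings if include(d) and d.mask.any()]
    if not kept:
        raise ValueError("no drawings survive the filter")
    if len(kept) == 1:
        counts = np.ones(len(cutoffs), dtype=int)
    else:
        Dm = build_dissimilarity_matrix(kept, include=None)
        tree = complete_linkage(Dm)
        counts = np.array([cluster_count(tree, c) for c in cutoffs])
    return ClusterCurve(
        cutoffs=np.asarray(cutoffs, dtype=float),
        counts=counts,
        system_id=system_id,
        session_id=session_id,
        subset=subset,
    )


def summarize_sessions(
    curves: Sequence[ClusterCurve], cutoffs: Sequence[float] = (0.7, 0.9)
) -> dict[str, dict[float, tuple[float, float]]]:
    """Mean +/- SE of cluster counts across sessions, per system per cutoff.

    SE is the sample standard deviation over sessions divided by sqrt(k);
    a single session yields SE = 0.
    """
    by_system: dict[str, list[ClusterCurve]] = {}
    for c in curves:
        by_system.setdefault(c.system_id, []).append(c)
    out: dict[str, dict[float, tuple[float, float]]] = {}
    for system, group in by_system.items():
        out[system] = {}
        for cutoff in cutoffs:
            vals = np.array([c.count_at(cutoff) for c in group], dtype=float)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            out[system][float(cutoff)] = (mean, se)
    return out
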