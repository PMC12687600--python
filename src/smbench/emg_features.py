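"""Waveform-length EMG features and supervised training-set assembly.

Intramuscular EMG recorded at 1 kHz is reduced to waveform-length (WFL)
features — the mean absolute difference between successive samples over a
100 ms window, updated every 50 ms (20 Hz frame rate) — the feature a
sense lead streams at 10-bit resolution.  Training data come from prompted
posture trials: 10 repetitions of 32 postures (all single and paired
movements over 4 DOFs), each trial 5 s = 2 s relax, 2 s move, 1 s relax.

This module also implements the data-hygiene steps applied before
controller training: dropping the least-similar repetition per posture,
flagging non-responsive (noise-only) channels, the anatomical 14/10/8
channel subsets, and assembly of (X, Y) pairs where Y is normalized user
effort times the posture direction vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FS_RAW",
    "FRAME_RATE",
    "WINDOW_MS",
    "UPDATE_MS",
    "FRAMES_PER_TRIAL",
    "REST_FRAMES",
    "MOVE_FRAMES",
    "RETAINED_FRAMES",
    "CHANNEL_MUSCLES",
    "CHANNEL_SUBSETS",
    "EmgTrial",
    "TrainingSet",
    "waveform_length",
    "quantize_10bit",
    "exclude_outlier_repetition",
    "detect_nonresponsive_channels",
    "build_training_set",
    "enumerate_postures",
]

FS_RAW = 1000          # raw EMG sample rate, Hz
FRAME_RATE = 20        # WFL frame rate, Hz (50 ms update)
WINDOW_MS = 100
UPDATE_MS = 50
FRAMES_PER_TRIAL = 100  # 5 s at 20 Hz

# 0-based frame windows within a 5-s trial (frames 0..99):
# 2 s pre-movement rest, 2 s movement, 1 s post-movement rest.
REST_FRAMES = np.arange(0, 40)
MOVE_FRAMES = np.arange(40, 80)
# Training retains the middle 3 s (first and last second excluded).
RETAINED_FRAMES = np.arange(20, 80)

DOF_NAMES = (
    "wrist_pronation_supination",
    "wrist_flexion_extension",
    "thumb",
    "fingers",
)

#: Anatomical muscle per intramuscular EMG channel, in recording order.
CHANNEL_MUSCLES = (
    "FPL", "PronatorTeres", "FCR", "FCU",
    "FDS", "FDS", "FDS", "FDS",
    "EDC", "EDC", "EDC", "EDC",
    "Supinator", "ECRL", "ECRB", "ECU",
)

# Controller channel subsets (0-based indices into the 16 channels).
# 14-ch: the responsive channels (two noise-only FDS channels excluded).
# 10-ch: additionally drop redundant FDS/EDC channels so each muscle keeps
#        one channel.  8-ch: additionally drop FPL and ECRB.
_CH14 = (0, 1, 2, 3, 4, 6, 8, 9, 10, 11, 12, 13, 14, 15)
_CH10 = (0, 1, 2, 3, 4, 8, 12, 13, 14, 15)
_CH8 = (1, 2, 3, 4, 8, 12, 13, 15)
CHANNEL_SUBSETS: dict[str, tuple[int, ...]] = {
    "table_14ch": _CH14,
    "table_10ch": _CH10,
    "table_8ch": _CH8,
}


@dataclass(frozen=True)
class EmgTrial:
    """One prompted-posture recording: raw EMG and/or its WFL frames."""

    posture: tuple[int, int, int, int]
    rep_index: int
    wfl: np.ndarray                   # channels x 100 frames
    raw: np.ndarray | None = None     # channels x 5000 samples, optional

    def __post_init__(self):
        posture = tuple(int(p) for p in self.posture)
        if len(posture) != 4 or any(p not in (-1, 0, 1) for p in posture):
            raise ValueError(f"posture must be 4 elements in {{-1,0,1}}: {posture}")
        object.__setattr__(self, "posture", posture)
        wfl = np.asarray(self.wfl, dtype=float)
        object.__setattr__(self, "wfl", wfl)
        if wfl.ndim != 2 or wfl.shape[1] != FRAMES_PER_TRIAL:
            raise ValueError(
                f"wfl must be channels x {FRAMES_PER_TRIAL} frames, got {wfl.shape}"
            )
        if np.any(wfl < 0):
            raise ValueError("WFL values must be non-negative")
        if self.raw is not None:
            raw = np.asarray(self.raw, dtype=float)
            object.__setattr__(self, "raw", raw)
            if raw.shape != (wfl.shape[0], 5 * FS_RAW):
                raise ValueError(
                    f"raw must be {wfl.shape[0]} x {5 * FS_RAW}, got {raw.shape}"
                )

    @property
    def n_channels(self) -> int:
        return self.wfl.shape[0]

    @classmethod
    def from_raw(
        cls, raw: np.ndarray, posture: Sequence[int], rep_index: int
    ) -> "EmgTrial":
        raw = np.asarray(raw, dtype=float)
        wfl = np.stack([waveform_length(ch) for ch in raw])
        return cls(posture=tuple(posture), rep_index=rep_index, wfl=wfl, raw=raw)


def waveform_length(
    signal: np.ndarray, window_ms: int = WINDOW_MS, update_ms: int = UPDATE_MS,
    fs: int = FS_RAW,
) -> np.ndarray:
    """WFL frame series of a 1-D raw EMG signal.

    Frame t is the mean absolute successive-sample difference over the
    causal ``window_ms`` window ending at sample ``(t+1) * update``, so a
    5 s signal yields exactly 100 frames at the 50 ms update rate.  Early
    frames whose full window would precede the signal use the available
    (truncated) window, which keeps the closed forms exact everywhere:
    a constant signal gives 0, a ramp of slope d per sample gives d, and
    a +/-A alternation gives 2A, in every frame.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    window = int(round(window_ms * fs / 1000))
    update = int(round(update_ms * fs / 1000))
    if window <= 1 or update < 1:
        raise ValueError("window/update too small at this sample rate")
    if x.size < window:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {window}-sample window"
        )
    absdiff = np.abs(np.diff(x))
    csum = np.concatenate([[0.0], np.cumsum(absdiff)])
    n_frames = x.size // update
    ends = update * np.arange(1, n_frames + 1)          # window end (exclusive)
    starts = np.maximum(0, ends - window)               # window start
    # diffs inside [s, e) are indices s..e-2, i.e. csum[e-1] - csum[s]
    return (csum[ends - 1] - csum[starts]) / (ends - 1 - starts)


def quantize_10bit(wfl: np.ndarray, full_scale: float) -> np.ndarray:
    """Clip to [0, full_scale] and round to the 1024-level (10-bit) grid."""
    if full_scale <= 0:
        raise ValueError("full_scale must be positive")
    levels = 1023
    clipped = np.clip(np.asarray(wfl, dtype=float), 0.0, full_scale)
    return np.round(clipped / full_scale * levels) / levels * full_scale


def _rep_feature(trial: EmgTrial) -> np.ndarray:
    """Channelwise mean WFL over the movement window."""
    return trial.wfl[:, MOVE_FRAMES].mean(axis=1)


def exclude_outlier_repetition(reps: Sequence[EmgTrial]) -> list[EmgTrial]:
    """Drop the repetition least similar to the others for one posture.

    Similarity of a repetition is the mean Pearson correlation between its
    channelwise movement-window WFL pattern and each other repetition's
    pattern; the repetition with the lowest mean similarity is excluded
    (ties, including the all-identical degenerate case where correlations
    are undefined, resolve to the lowest rep_index).
    """
    if len(reps) < 2:
        raise ValueError("need at least 2 repetitions to exclude an outlier")
    feats = np.stack([_rep_feature(t) for t in reps])
    n = len(reps)
    sims = np.zeros(n)
    for i in range(n):
        cors = []
        for j in range(n):
            if i == j:
                continue
            a, b = feats[i], feats[j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                cors.append(1.0 if np.allclose(a, b) else 0.0)
            else:
                cors.append(float(np.corrcoef(a, b)[0, 1]))
        sims[i] = np.mean(cors)
    order = sorted(range(n), key=lambda i: (sims[i], reps[i].rep_index))
    drop = order[0]
    return [t for i, t in enumerate(reps) if i != drop]


def detect_nonresponsive_channels(
    trials: Sequence[EmgTrial], threshold: float = 1.2
) -> tuple[np.ndarray, np.ndarray]:
    """Flag channels whose EMG does not modulate with movement.

    For each channel the movement/rest WFL ratio is computed per trial and
    averaged over all trials; channels whose mean ratio falls below
    ``threshold`` are flagged as noise-only.  Returns ``(flags, ratios)``.
    """
    if not trials:
        raise ValueError("no trials given")
    move = np.stack([t.wfl[:, MOVE_FRAMES].mean(axis=1) for t in trials])
    rest = np.stack([t.wfl[:, REST_FRAMES].mean(axis=1) for t in trials])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(rest > 0, move / rest, np.inf)
    mean_ratio = ratios.mean(axis=0)
    return mean_ratio < threshold, mean_ratio


@dataclass(frozen=True)
class TrainingSet:
    """Aligned (X, Y) supervised pairs with a 70/15/15 frame split."""

    X: np.ndarray                 # frames x n_channels WFL
    Y: np.ndarray                 # frames x 4 effort vectors
    channel_ids: tuple[int, ...]
    normalizer: float
    split: np.ndarray             # per-frame label in {"train","val","test"}

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "split", np.asarray(self.split))
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        if X.shape[0] != Y.shape[0] or self.split.shape[0] != X.shape[0]:
            raise ValueError("X, Y and split must have aligned rows")
        if Y.shape[1] != 4:
            raise ValueError("Y must have 4 columns")
        if np.any(np.abs(Y) > 1 + 1e-9):
            raise ValueError("effort vectors must lie in [-1, 1]")

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.X[m], self.Y[m]


def build_training_set(
    trials: Sequence[EmgTrial],
    channels: Sequence[int] | str,
    normalizer: float | None = None,
    *,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    trialwise_split: bool = False,
) -> TrainingSet:
    """Assemble supervised (WFL, effort-vector) pairs from posture trials.

    Per retained frame (middle 3 s of each trial): the input is the WFL of
    the selected channels; scalar user effort is the mean WFL over those
    channels divided by ``normalizer`` and clipped to [0, 1]; the output is
    effort times the 4-element posture direction vector.  Frames are pooled
    over trials and assigned to train/val/test at 70/15/15, frame-wise
    i.i.d. by default, trial-wise with ``trialwise_split=True`` for
    leakage-aware evaluation.

    ``normalizer=None`` uses the 95th percentile of mean-WFL over all
    movement-window frames (so peak efforts map near 1).
    """
    if isinstance(channels, str):
        channels = CHANNEL_SUBSETS[channels]
    channels = tuple(int(c) for c in channels)
    if not channels:
        raise ValueError("channel subset is empty")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")

    if normalizer is None:
        move_effort = np.concatenate(
            [t.wfl[np.ix_(channels, MOVE_FRAMES)].mean(axis=0) for t in trials]
        )
        normalizer = float(np.percentile(move_effort, 95))
    if normalizer <= 0:
        raise ValueError("effort normalizer must be positive")

    X_parts, Y_parts, trial_of_frame = [], [], []
    for k, t in enumerate(trials):
        frames = t.wfl[np.ix_(channels, RETAINED_FRAMES)].T  # 60 x n_ch
        effort = np.clip(frames.mean(axis=1) / normalizer, 0.0, 1.0)
        X_parts.append(frames)
        Y_parts.append(effort[:, None] * np.asarray(t.posture, dtype=float))
        trial_of_frame.append(np.full(frames.shape[0], k))
    X = np.concatenate(X_parts)
    Y = np.concatenate(Y_parts)
    trial_of_frame = np.concatenate(trial_of_frame)

    rng = np.random.default_rng(seed)
    names = np.array(["train", "val", "test"])
    if trialwise_split:
        n_tr = len(trials)
        order = rng.permutation(n_tr)
        bounds = np.floor(np.cumsum(np.asarray(split_fractions) * n_tr)).astype(int)
        trial_split = np.empty(n_tr, dtype=object)
        trial_split[order[: bounds[0]]] = "train"
        trial_split[order[bounds[0]: bounds[1]]] = "val"
        trial_split[order[bounds[1]:]] = "test"
        split = np.array([trial_split[k] for k in trial_of_frame])
    else:
        n = X.shape[0]
        order = rng.permutation(n)
        n_train = int(round(split_fractions[0] * n))
        n_val = int(round(split_fractions[1] * n))
        split = np.empty(n, dtype=object)
        split[order[:n_train]] = "train"
        split[order[n_train: n_train + n_val]] = "val"
        split[order[n_train + n_val:]] = "test"
    return TrainingSet(
        X=X, Y=Y, channel_ids=channels, normalizer=float(normalizer),
        split=split.astype(str),
    )


def enumerate_postures() -> list[tuple[int, int, int, int]]:
    """All 32 single and paired movements over the 4 DOFs.

    Singles (one nonzero element, 8 postures) ordered by DOF then sign
    (-1 before +1); pairs (two nonzero elements, 24 postures) ordered
    lexicographically by DOF-index pair then by the sign combination.
    """
    postures: list[tuple[int, int, int, int]] = []
    for d in range(4):
        for s in (-1, 1):
            v = [0, 0, 0, 0]
            v[d] = s
            postures.append(tuple(v))
    for d1, d2 in combinations(range(4), 2):
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                v = [0, 0, 0, 0]
                v[d1], v[d2] = s1, s2
                postures.append(tuple(v))
    return postures
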