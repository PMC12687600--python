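"""Synthetic data generators for the percept and control analyses.

No public dataset exists for the single-participant study conditions these
analyses target, so every upstream input is generated here with the
statistical structure the analyses assume:

* a procedurally drawn two-panel hand template (palmar left, dorsal
  right) with labeled digit/palm zones and a wrist row, calibrated to a
  19.0 cm wrist-to-middle-fingertip length;
* percept drawings under a parameterized electrode model — contacts are
  placed somatotopically along a 1-D nerve-cross-section coordinate
  mapped to hand regions, evoke elliptical blobs with log-normally
  distributed areas, and jitter between sessions;
* synergy-driven intramuscular EMG: per-channel amplitude-modulated white
  noise whose amplitude follows a rectified muscle-synergy drive of the
  4-DOF effort vector, including dead (noise-only) channels;
* a closed-loop synthetic user emitting WFL frames from a proportional
  error-correcting policy through the same forward model; and
* a deterministic psychophysical observer plus the amplitude-staircase /
  pulse-width-bisection threshold search procedure.

All generators are reproducible bit-for-bit under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .emg_features import CHANNEL_MUSCLES, EmgTrial, enumerate_postures
from .percept_maps import (
    HandTemplate,
    PerceptDrawing,
    SessionRecord,
    categorize,
    clip_to_hand,
)

__all__ = [
    "generate_hand_template",
    "ElectrodeModel",
    "percutaneous_16ch_model",
    "isens_60contact_model",
    "generate_percept_sessions",
    "SynergyModel",
    "default_synergy_model",
    "generate_emg_dataset",
    "SyntheticUser",
    "forward_wfl",
    "ThresholdObserver",
    "ThresholdSearchResult",
    "simulate_threshold_search",
]


# ---------------------------------------------------------------------------
# Hand template
# ---------------------------------------------------------------------------

# Normalized single-panel geometry (row, col in [0, 1], fingertips up).
_WRIST_R = 0.93
_DIGITS = {
    # name: (base_r, base_c, tip_r, tip_c, half_width)
    "thumb": (0.66, 0.27, 0.46, 0.10, 0.050),
    "index": (0.52, 0.33, 0.17, 0.31, 0.042),
    "middle": (0.52, 0.46, 0.08, 0.46, 0.044),
    "ring": (0.52, 0.59, 0.14, 0.60, 0.042),
    "little": (0.54, 0.71, 0.26, 0.73, 0.038),
}
_PALM = (0.715, 0.485, 0.215, 0.235)  # center_r, center_c, semi_r, semi_c
_FOREARM = (0.93, 1.0, 0.36, 0.62)    # r0, r1, c0, c1


def _capsule_mask(rr, cc, p0, p1, w):
    """Points within distance w of segment p0-p1 (normalized coords)."""
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    proj_r = p0[0] + t * d[0]
    proj_c = p0[1] + t * d[1]
    return (rr - proj_r) ** 2 + (cc - proj_c) ** 2 <= w**2


def generate_hand_template(resolution: int = 256, seed: int = 0) -> HandTemplate:
    """Procedural two-panel hand silhouette raster.

    ``resolution`` is the square panel size in pixels; the raster is
    ``resolution x 2*resolution`` with the palmar panel on the left and the
    (mirrored) dorsal panel on the right.  The geometry is defined in
    normalized coordinates, so coverage statistics are resolution-stable.
    ``seed`` is accepted for interface uniformity; the silhouette is
    deterministic.
    """
    del seed  # geometry is fixed; deterministic by construction
    n = int(resolution)
    if n < 32:
        raise ValueError("panel resolution must be at least 32 px")
    centers = (np.arange(n) + 0.5) / n
    rr, cc = np.meshgrid(centers, centers, indexing="ij")

    region = np.full((n, n), "background", dtype=object)
    palm = ((rr - _PALM[0]) / _PALM[2]) ** 2 + ((cc - _PALM[1]) / _PALM[3]) ** 2 <= 1
    palm &= rr < _WRIST_R
    region[palm] = "palm"
    for name, (r0, c0, r1, c1, w) in _DIGITS.items():
        m = _capsule_mask(rr, cc, (r0, c0), (r1, c1), w)
        region[m] = name
    forearm = (
        (rr >= _FOREARM[0]) & (rr <= _FOREARM[1])
        & (cc >= _FOREARM[2]) & (cc <= _FOREARM[3])
    )
    region[forearm & (region == "background")] = "forearm"

    panel_mask = region != "background"
    # dorsal panel mirrors the palmar silhouette left-right
    mask = np.concatenate([panel_mask, panel_mask[:, ::-1]], axis=1)
    region_full = np.concatenate([region, region[:, ::-1]], axis=1)
    labels = np.full(mask.shape, "background", dtype=object)
    labels[:, :n][panel_mask] = "palmar"
    labels[:, n:][panel_mask[:, ::-1]] = "dorsal"

    wrist_row = int(np.floor(_WRIST_R * n))
    middle_cols = np.any(region_full == "middle", axis=1)
    tip_row = int(np.argmax(middle_cols))
    cm_per_pixel = 19.0 / float(wrist_row - tip_row)
    return HandTemplate(
        mask=mask,
        panel_labels=labels,
        wrist_row=wrist_row,
        cm_per_pixel=cm_per_pixel,
        region_labels=region_full,
    )


# ---------------------------------------------------------------------------
# Electrode models and percept-session generation
# ---------------------------------------------------------------------------

# Somatotopic anchor polylines per nerve: (panel, row, col) waypoints in
# normalized coordinates.  Contact index maps to arc-length fraction along
# the polyline, mirroring the 1-D somatotopic ordering of axons in a
# nerve cross-section.  Median innervates the radial palmar hand (thumb
# through middle finger), ulnar the ulnar palmar hand (ring/little and
# hypothenar), radial the dorsum (and, often, only the residual limb —
# modeled as a high no-hand-percept probability).
_NERVE_ANCHORS: dict[str, list[tuple[int, float, float]]] = {
    "median": [
        (0, 0.52, 0.14),
        (0, 0.66, 0.33),
        (0, 0.72, 0.46),
        (0, 0.40, 0.34),
        (0, 0.25, 0.46),
    ],
    "ulnar": [
        (0, 0.78, 0.60),
        (0, 0.60, 0.64),
        (0, 0.40, 0.61),
        (0, 0.33, 0.72),
    ],
    "radial": [
        (1, 0.75, 0.45),
        (1, 0.55, 0.52),
        (1, 0.35, 0.60),
    ],
}


def _anchor_point(nerve: str, frac: float) -> tuple[int, float, float]:
    """Interpolate a somatotopic position at arc-length fraction ``frac``."""
    pts = _NERVE_ANCHORS[nerve]
    panels = [p[0] for p in pts]
    xy = np.array([(p[1], p[2]) for p in pts])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = frac * cum[-1]
    k = int(np.searchsorted(cum[1:], s, side="left"))
    k = min(k, len(seg) - 1)
    t = (s - cum[k]) / seg[k]
    r, c = xy[k] * (1 - t) + xy[k + 1] * t
    return panels[k], float(r), float(c)


@dataclass(frozen=True)
class ContactSpec:
    contact_id: str
    nerve: str
    electrode_id: str
    somatotopic_frac: float  # position along the nerve's anchor polyline


@dataclass(frozen=True)
class ElectrodeModel:
    """Parameterized model of what a set of stimulation contacts evokes.

    ``area_fraction_mean`` is the median single-contact percept area as a
    fraction of total (two-panel) hand area; areas are log-normal with
    log-space sigma ``area_sigma``.  ``p_no_percept`` (per nerve) is the
    probability a contact evokes no hand percept in a session.
    ``jitter_frac`` is the session-to-session percept-center jitter in
    normalized panel units.
    """

    contacts: tuple[ContactSpec, ...]
    area_fraction_mean: float = 0.03
    area_sigma: float = 0.4
    p_no_percept: dict = field(default_factory=dict)  # nerve -> prob
    p_proprioceptive: float = 0.08
    p_painful: float = 0.04
    proprio_area_multiplier: float = 6.0
    jitter_frac: float = 0.02

    def __post_init__(self):
        if not (0 < self.area_fraction_mean < 1):
            raise ValueError("area_fraction_mean must lie in (0, 1)")
        for p in (self.p_proprioceptive, self.p_painful, *self.p_no_percept.values()):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


def _spread_contacts(
    nerve: str, electrode_id: str, n: int, prefix: str
) -> list[ContactSpec]:
    return [
        ContactSpec(
            contact_id=f"{prefix}{i + 1}",
            nerve=nerve,
            electrode_id=electrode_id,
            somatotopic_frac=(i + 0.5) / n,
        )
        for i in range(n)
    ]


def percutaneous_16ch_model(**overrides) -> ElectrodeModel:
    """16 stimulating contacts: one 8-contact cuff each on median and ulnar.

    Sparse contact spacing and small percept areas; every contact evokes a
    percept, emulating the earlier-generation system's behaviour.
    """
    contacts = (
        *_spread_contacts("median", "M-FINE", 8, "M"),
        *_spread_contacts("ulnar", "U-FINE", 8, "U"),
    )
    params = dict(
        contacts=tuple(contacts),
        area_fraction_mean=0.03,
        p_no_percept={"median": 0.0, "ulnar": 0.0, "radial": 0.6},
    )
    params.update(overrides)
    return ElectrodeModel(**params)


def isens_60contact_model(**overrides) -> ElectrodeModel:
    """60 tested contacts: four 15-contact cuffs (2 median, 1 ulnar, 1 radial).

    Dense spacing gives overlapping percepts with larger areas; the radial
    cuff mostly fails to evoke hand percepts (residual-limb percepts fall
    outside the hand template and appear as no-hand-percept contacts).
    """
    contacts = (
        *_spread_contacts("median", "M-CFINE-prox", 15, "MP"),
        *_spread_contacts("median", "M-CFINE-dist", 15, "MD"),
        *_spread_contacts("ulnar", "U-CFINE", 15, "UC"),
        *_spread_contacts("radial", "R-CFINE", 15, "RC"),
    )
    params = dict(
        contacts=tuple(contacts),
        area_fraction_mean=0.08,
        p_no_percept={"median": 0.0, "ulnar": 0.1, "radial": 0.7},
        p_proprioceptive=0.10,
    )
    params.update(overrides)
    return ElectrodeModel(**params)


def _blob_mask(
    template: HandTemplate,
    panel: int,
    center_rc: tuple[float, float],
    target_area_px: float,
    ratio: float,
    theta: float,
) -> np.ndarray:
    """Rasterize an elliptical percept blob clipped to the hand region.

    The ellipse is iteratively rescaled (bounded bisection) so the clipped
    pixel area approximates the sampled target area even when the blob
    overhangs the silhouette boundary.
    """
    n = template.mask.shape[0]
    hand = template.hand_region
    col0 = panel * n
    r0 = center_rc[0] * n
    c0 = center_rc[1] * n + col0
    b = np.sqrt(target_area_px / (np.pi * ratio))
    a = ratio * b
    rows = np.arange(n) + 0.5
    cols = np.arange(2 * n) + 0.5
    cc, rr = np.meshgrid(cols, rows)
    ct, st = np.cos(theta), np.sin(theta)
    u = (rr - r0) * ct + (cc - c0) * st
    v = -(rr - r0) * st + (cc - c0) * ct
    ell_dist2 = (u / a) ** 2 + (v / b) ** 2

    # bisect a scale factor on the axes so the clipped area hits the target
    lo, hi = 1.0, 4.0
    if (((ell_dist2 <= 1.0) & hand).sum()) >= target_area_px:
        lo, hi = 0.25, 1.0
    for _ in range(12):
        s = 0.5 * (lo + hi)
        if (((ell_dist2 <= s**2) & hand).sum()) < target_area_px:
            lo = s
        else:
            hi = s
    return (ell_dist2 <= hi**2) & hand


def generate_percept_sessions(
    model: ElectrodeModel,
    template: HandTemplate,
    n_sessions: int = 3,
    seed: int = 0,
    *,
    system_id: str = "system",
) -> list[SessionRecord]:
    """Simulate percept drawings for ``n_sessions`` sessions of one system.

    Per session, per contact: a Bernoulli draw decides whether a hand
    percept is evoked; if so an elliptical blob is placed at the contact's
    somatotopic position plus session jitter, with a log-normal area and
    sampled quality categories.  Blob shape (aspect ratio, orientation) is
    a fixed per-contact property, so with zero jitter the same contact
    evokes an identical percept in every session.  Contacts evoking
    nothing stay in ``tested_contacts`` only.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    hand_px = template.total_hand_area_px
    shape_of = {
        c.contact_id: (rng.uniform(1.0, 2.0), rng.uniform(0, np.pi))
        for c in model.contacts
    }
    sessions = []
    for s in range(n_sessions):
        session_id = f"session{s + 1}"
        drawings = []
        for contact in model.contacts:
            p_none = model.p_no_percept.get(contact.nerve, 0.0)
            if rng.random() < p_none:
                continue
            panel, r, c = _anchor_point(contact.nerve, contact.somatotopic_frac)
            r += rng.normal(0, model.jitter_frac)
            c += rng.normal(0, model.jitter_frac)
            r = float(np.clip(r, 0.05, _WRIST_R - 0.05))
            c = float(np.clip(c, 0.05, 0.95))
            area_frac = model.area_fraction_mean * rng.lognormal(0.0, model.area_sigma)
            u = rng.random()
            if u < model.p_painful:
                qualities = frozenset({"burning", "stinging"})
            elif u < model.p_painful + model.p_proprioceptive:
                qualities = frozenset({"joint movement"})
                area_frac = min(area_frac * model.proprio_area_multiplier, 0.9)
            else:
                qualities = frozenset({"pressure"})
            area_frac = min(area_frac, 0.9)
            ratio, theta = shape_of[contact.contact_id]
            mask = _blob_mask(
                template, panel, (r, c), area_frac * hand_px, ratio, theta
            )
            if not mask.any():
                continue
            drawing = PerceptDrawing(
                contact_id=contact.contact_id,
                nerve=contact.nerve,
                electrode_id=contact.electrode_id,
                session_id=session_id,
                system_id=system_id,
                mask=mask,
                qualities=qualities,
                categories=categorize(qualities),
            )
            drawings.append(clip_to_hand(drawing, template))
        sessions.append(
            SessionRecord(
                system_id=system_id,
                session_id=session_id,
                drawings=tuple(drawings),
                tested_contacts=tuple(c.contact_id for c in model.contacts),
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Synergy-driven EMG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyModel:
    """Rectified synergy map from 4-DOF effort vectors to channel amplitudes.

    ``W_pos[c, d]`` (``W_neg[c, d]``) is channel c's non-negative drive
    when DOF d moves in the positive (negative) direction; the channel's
    noise amplitude for effort vector y is

        amp_c = gain_c * (sum_d W_pos[c,d]*max(y_d,0) + W_neg[c,d]*max(-y_d,0)
                          + crosstalk + floor)

    Dead channels ignore the drive and emit floor-amplitude noise only.
    Raw EMG is amplitude-modulated zero-mean white noise, whose expected
    WFL is (2/sqrt(pi)) times the amplitude — so WFL rises linearly with
    activation by construction.
    """

    W_pos: np.ndarray
    W_neg: np.ndarray
    gains: np.ndarray
    noise_floor: float = 0.05
    crosstalk: float = 0.05
    dead_channels: frozenset[int] = frozenset()
    channel_muscles: tuple[str, ...] = CHANNEL_MUSCLES

    def __post_init__(self):
        W_pos = np.asarray(self.W_pos, dtype=float)
        W_neg = np.asarray(self.W_neg, dtype=float)
        gains = np.asarray(self.gains, dtype=float)
        object.__setattr__(self, "W_pos", W_pos)
        object.__setattr__(self, "W_neg", W_neg)
        object.__setattr__(self, "gains", gains)
        object.__setattr__(self, "dead_channels", frozenset(self.dead_channels))
        if W_pos.shape != W_neg.shape or W_pos.shape[1] != 4:
            raise ValueError("W_pos/W_neg must be n_channels x 4")
        if np.any(W_pos < 0) or np.any(W_neg < 0):
            raise ValueError("synergy weights must be non-negative")
        if gains.shape != (W_pos.shape[0],):
            raise ValueError("per-channel gains must match channel count")
        if not self.dead_channels <= set(range(self.n_channels)):
            raise ValueError("dead channels out of range")

    @property
    def n_channels(self) -> int:
        return self.W_pos.shape[0]

    def amplitude(self, effort: np.ndarray) -> np.ndarray:
        """Per-channel noise amplitude for a 4-DOF effort vector."""
        y = np.asarray(effort, dtype=float)
        drive = self.W_pos @ np.maximum(y, 0) + self.W_neg @ np.maximum(-y, 0)
        # crosstalk: each channel picks up a fraction of its neighbours' drive
        leak = self.crosstalk * (np.roll(drive, 1) + np.roll(drive, -1)) / 2
        amp = drive + leak
        amp[list(self.dead_channels)] = 0.0
        return self.gains * (amp + self.noise_floor)


def default_synergy_model(
    dead_channels: Sequence[int] = (5, 7), seed: int = 0
) -> SynergyModel:
    """The study-condition synergy layout over the 16 intramuscular channels.

    DOF sign convention: +1 = supination, wrist extension, thumb
    abduction/extension, finger extension.  FPL drives thumb flexion and
    ECRB carries the dominant thumb-extension drive (with a secondary
    wrist-extension role), so dropping both removes the thumb DOF's
    information — the stylized counterpart of the muscle roles behind the
    8-channel controller's deficit.  The two dead channels default to the
    FDS pair excluded from every controller.
    """
    n = len(CHANNEL_MUSCLES)
    W_pos = np.zeros((n, 4))
    W_neg = np.zeros((n, 4))
    # DOF order: [pron-sup, wrist flex-ext, thumb, fingers]
    W_neg[0, 2] = 1.0          # FPL: thumb flexion
    W_neg[1, 0] = 1.0          # pronator teres: pronation
    W_neg[2, 1] = 1.0          # FCR: wrist flexion
    W_neg[3, 1] = 1.0          # FCU: wrist flexion
    for c in range(4, 8):      # FDS x4: finger flexion
        W_neg[c, 3] = 1.0
    for c in range(8, 12):     # EDC x4: finger extension
        W_pos[c, 3] = 1.0
    W_pos[12, 0] = 1.0         # supinator: supination
    W_pos[13, 1] = 1.0         # ECRL: wrist extension
    W_pos[14, 2] = 1.0         # ECRB: thumb extension (dominant drive here)
    W_pos[14, 1] = 0.3         # ... plus a secondary wrist-extension role
    W_pos[15, 1] = 1.0         # ECU: wrist extension
    rng = np.random.default_rng(seed)
    gains = rng.uniform(0.8, 1.2, size=n)
    return SynergyModel(
        W_pos=W_pos, W_neg=W_neg, gains=gains,
        dead_channels=frozenset(dead_channels),
    )


_WFL_OF_UNIT_NOISE = 2.0 / np.sqrt(np.pi)  # E|N(0,s)-N(0,s)'| = 2s/sqrt(pi)


def _effort_profile(n_samples: int = 5000, e_max: float = 1.0) -> np.ndarray:
    """Scalar effort per raw sample: rest 2 s, ramp to e_max over 2 s,
    rest 1 s."""
    e = np.zeros(n_samples)
    move = slice(2000, 4000)
    e[move] = np.linspace(0.0, e_max, 2000)
    return e


def generate_emg_dataset(
    model: SynergyModel,
    postures: Sequence[Sequence[int]] | None = None,
    reps: int = 10,
    seed: int = 0,
    *,
    e_max: float = 1.0,
    rep_variability: float = 0.1,
) -> list[EmgTrial]:
    """Simulate the prompted-posture training recordings.

    Per trial the 4-DOF effort ramps from 0 to ``e_max`` during the 2 s
    movement window of the 5 s trial; each channel emits white noise whose
    amplitude follows the synergy drive (dead channels emit floor noise
    throughout).  ``rep_variability`` is the log-normal sigma of a
    per-repetition, per-channel gain wobble.  Returns ``len(postures) *
    reps`` trials.
    """
    if postures is None:
        postures = enumerate_postures()
    rng = np.random.default_rng(seed)
    profile = _effort_profile(e_max=e_max)
    trials = []
    for posture in postures:
        for rep in range(1, reps + 1):
            unit_amp = model.amplitude(np.asarray(posture, dtype=float))
            floor_amp = model.gains * model.noise_floor
            wobble = rng.lognormal(0.0, rep_variability, size=model.n_channels)
            # amplitude(t) interpolates floor -> full drive with effort
            amp_t = (
                floor_amp[:, None]
                + (unit_amp - floor_amp)[:, None] * profile[None, :]
            ) * wobble[:, None]
            raw = amp_t * rng.standard_normal(amp_t.shape)
            trials.append(
                EmgTrial.from_raw(raw, posture=tuple(posture), rep_index=rep)
            )
    return trials


def forward_wfl(
    model: SynergyModel,
    effort: np.ndarray,
    rng: np.random.Generator | None = None,
    noise: float = 0.1,
) -> np.ndarray:
    """Expected WFL frame for an effort vector, with multiplicative noise.

    This is the analytic image of the raw-EMG generator: the WFL of
    amplitude-a white noise is (2/sqrt(pi)) * a in expectation.
    """
    frame = _WFL_OF_UNIT_NOISE * model.amplitude(effort)
    if rng is not None and noise > 0:
        frame = frame * rng.lognormal(0.0, noise, size=frame.shape)
    return frame


@dataclass
class SyntheticUser:
    """Proportional error-correcting stand-in for the participant.

    Intended effort per DOF is ``clip(kp * (target - state), -1, 1)``; the
    emitted WFL frame is the synergy forward model of that effort with
    multiplicative log-normal noise.  Stateless across frames apart from
    the seeded noise stream.
    """

    model: SynergyModel
    channels: Sequence[int] | None = None  # subset the controller reads
    kp: float = 2.0
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)

    def __call__(self, state: np.ndarray, target: np.ndarray) -> np.ndarray:
        effort = np.clip(self.kp * (np.asarray(target) - np.asarray(state)), -1, 1)
        frame = forward_wfl(self.model, effort, self._rng, self.noise)
        if self.channels is not None:
            frame = frame[list(self.channels)]
        return frame


# ---------------------------------------------------------------------------
# Psychophysical threshold search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdObserver:
    """Deterministic observer: detects a stimulus iff its charge
    (amplitude x pulse width) reaches the charge threshold."""

    charge_threshold: float  # mA * us

    def detects(self, amplitude_ma: float, pulse_width_us: float) -> bool:
        return amplitude_ma * pulse_width_us >= self.charge_threshold

    def min_pulse_width(self, amplitude_ma: float) -> float:
        return self.charge_threshold / amplitude_ma


@dataclass(frozen=True)
class ThresholdSearchResult:
    detected: bool
    amplitude_ma: float | None
    pulse_width_us: float | None
    n_queries: int


def simulate_threshold_search(
    observer: ThresholdObserver,
    amplitude_step_ma: float = 0.1,
    pw_resolution_us: float = 5.0,
    *,
    amplitude_max_ma: float = 1.0,
    pw_max_us: float = 255.0,
) -> ThresholdSearchResult:
    """Amplitude staircase, then pulse-width bisection, to detection
    threshold.

    Phase 1 raises the amplitude from one step in ``amplitude_step_ma``
    increments at the maximum pulse width until the observer detects; if
    the maximum amplitude fails, the contact yields no percept.  Phase 2
    bisects the pulse width (increase halfway up the remaining range on a
    miss, decrease halfway on a hit) until the bracket is within
    ``pw_resolution_us``, returning the lowest detected pulse width —
    guaranteed within the resolution of the observer's true minimum.
    """
    if amplitude_step_ma <= 0 or pw_resolution_us <= 0:
        raise ValueError("step sizes must be positive")
    n_queries = 0
    amplitude = None
    n_steps = int(round(amplitude_max_ma / amplitude_step_ma))
    for k in range(1, n_steps + 1):
        amp = k * amplitude_step_ma
        n_queries += 1
        if observer.detects(amp, pw_max_us):
            amplitude = amp
            break
    if amplitude is None:
        return ThresholdSearchResult(False, None, None, n_queries)

    lo, hi = 0.0, pw_max_us  # lo: not detected, hi: detected
    while hi - lo > pw_resolution_us:
        mid = 0.5 * (lo + hi)
        n_queries += 1
        if observer.detects(amplitude, mid):
            hi = mid
        else:
            lo = mid
    return ThresholdSearchResult(True, amplitude, hi, n_queries)
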