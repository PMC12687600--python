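"""Percept-location maps on a common hand template.

Evoked sensory percepts are reported as free-hand drawings on a two-panel
(palmar/dorsal) hand silhouette.  This module represents those drawings as
binary rasters aligned to a shared :class:`HandTemplate` and computes the
coverage statistics used to compare stimulation systems: cumulative hand
coverage (union of drawings), per-pixel coverage density, and per-contact
percept areas in hand-fraction or cm^2 units.

Only locations distal to the wrist count as "hand"; drawings are clipped
before any area arithmetic.  Percepts are categorized as tactile,
proprioceptive and/or painful from the participant's free-text quality
descriptors via a configurable lexicon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "HandTemplate",
    "PerceptDrawing",
    "SessionRecord",
    "DEFAULT_QUALITY_LEXICON",
    "CATEGORIES",
    "clip_to_hand",
    "categorize",
    "cumulative_coverage",
    "coverage_density",
    "percept_area",
    "load_mask_png",
    "save_mask_png",
    "load_session_manifest",
]

CATEGORIES = ("tactile", "proprioceptive", "painful")

#: Default mapping from reported sensation-quality descriptors to percept
#: categories.  User-editable: pass your own mapping to :func:`categorize`.
DEFAULT_QUALITY_LEXICON: dict[str, frozenset[str]] = {
    "pressure": frozenset({"tactile"}),
    "touch": frozenset({"tactile"}),
    "tap": frozenset({"tactile"}),
    "tingling": frozenset({"tactile"}),
    "vibration": frozenset({"tactile"}),
    "buzzing": frozenset({"tactile"}),
    "movement": frozenset({"proprioceptive"}),
    "joint movement": frozenset({"proprioceptive"}),
    "joint": frozenset({"proprioceptive"}),
    "posture": frozenset({"proprioceptive"}),
    "flexing": frozenset({"proprioceptive"}),
    "pain": frozenset({"painful"}),
    "toothache pain": frozenset({"painful"}),
    "burning": frozenset({"painful"}),
    "stinging": frozenset({"painful"}),
    "ache": frozenset({"painful"}),
    "uncomfortable": frozenset({"painful"}),
}


class MaskShapeError(ValueError):
    """Raised when a drawing raster is not congruent with the template."""

    def __init__(self, mask_shape: tuple, template_shape: tuple):
        self.mask_shape = tuple(mask_shape)
        self.template_shape = tuple(template_shape)
        super().__init__(
            f"drawing mask shape {self.mask_shape} does not match hand "
            f"template shape {self.template_shape}"
        )


@dataclass(frozen=True)
class HandTemplate:
    """Two-panel hand silhouette: the shared coordinate frame for percepts.

    Parameters
    ----------
    mask
        2-D boolean raster, True on hand pixels (both panels, palmar left /
        dorsal right).
    panel_labels
        Per-pixel string label array: ``"palmar"``, ``"dorsal"`` or
        ``"background"``.
    wrist_row
        Row index of the wrist line.  Pixels at or below (``row >=
        wrist_row``) are proximal and excluded from hand-area analyses.
    cm_per_pixel
        Physical scale, calibrated so the wrist-to-middle-fingertip pixel
        distance equals the participant's sound-hand length of 19.0 cm.
    """

    mask: np.ndarray
    panel_labels: np.ndarray
    wrist_row: int
    cm_per_pixel: float
    region_labels: np.ndarray | None = None

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("template mask must be a nonempty 2-D raster")
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")
        labelled = np.asarray(self.panel_labels)
        if labelled.shape != mask.shape:
            raise MaskShapeError(labelled.shape, mask.shape)
        if np.any((labelled != "background") & ~mask):
            raise ValueError("panel-labelled pixels must lie on the hand mask")
        if self.total_hand_area_px == 0:
            raise ValueError("no hand pixels distal to the wrist row")

    @property
    def hand_region(self) -> np.ndarray:
        """Boolean raster of hand pixels distal to the wrist."""
        distal = np.zeros_like(self.mask)
        distal[: self.wrist_row, :] = True
        return self.mask & distal

    @property
    def total_hand_area_px(self) -> int:
        return int(self.hand_region.sum())

    @property
    def hand_area_cm2(self) -> float:
        return self.total_hand_area_px * self.cm_per_pixel**2


@dataclass(frozen=True)
class PerceptDrawing:
    """One stimulation contact's reported percept location in one session."""

    contact_id: str
    nerve: str
    mask: np.ndarray
    electrode_id: str = ""
    session_id: str = ""
    system_id: str = ""
    qualities: frozenset[str] = frozenset()
    categories: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        object.__setattr__(self, "qualities", frozenset(self.qualities))
        object.__setattr__(self, "categories", frozenset(self.categories))
        if self.nerve not in ("median", "ulnar", "radial"):
            raise ValueError(f"unknown nerve {self.nerve!r}")
        unknown = self.categories - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SessionRecord:
    """All percepts of one experimental session, plus contacts tested.

    Contacts that evoked no percept appear in ``tested_contacts`` but have
    no drawing, enabling "52 of 60 tested contacts evoked percepts"-style
    tallies.
    """

    system_id: str
    session_id: str
    drawings: tuple[PerceptDrawing, ...]
    tested_contacts: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "drawings", tuple(self.drawings))
        object.__setattr__(self, "tested_contacts", tuple(self.tested_contacts))
        tested = set(self.tested_contacts)
        seen = set()
        for d in self.drawings:
            if d.contact_id not in tested:
                raise ValueError(
                    f"drawing contact {d.contact_id!r} not in tested_contacts"
                )
            key = (d.contact_id, d.session_id)
            if key in seen:
                raise ValueError(f"duplicate drawing for {key}")
            seen.add(key)

    @property
    def n_evoked(self) -> int:
        return len({d.contact_id for d in self.drawings})


def clip_to_hand(drawing: PerceptDrawing, template: HandTemplate) -> PerceptDrawing:
    """Restrict a drawing to hand pixels distal to the wrist.

    Returns a new :class:`PerceptDrawing`; the input is unmodified.
    """
    if drawing.mask.shape != template.mask.shape:
        raise MaskShapeError(drawing.mask.shape, template.mask.shape)
    return replace(drawing, mask=drawing.mask & template.hand_region)


def categorize(
    qualities: Iterable[str],
    lexicon: Mapping[str, Iterable[str]] | None = None,
    *,
    unknown: str = "ignore",
) -> frozenset[str]:
    """Map free-text quality descriptors to percept categories.

    A descriptor may map to several categories; the result is the union
    over descriptors.  ``unknown`` is the fallback policy for descriptors
    absent from the lexicon: ``"ignore"`` skips them, ``"strict"`` raises.
    """
    if lexicon is None:
        lexicon = DEFAULT_QUALITY_LEXICON
    if unknown not in ("ignore", "strict"):
        raise ValueError(f"unknown policy {unknown!r}")
    out: set[str] = set()
    missing = []
    for q in qualities:
        key = q.strip().lower()
        if key in lexicon:
            out.update(lexicon[key])
        else:
            missing.append(q)
    if missing and unknown == "strict":
        raise KeyError(f"descriptors not in lexicon: {sorted(missing)}")
    bad = out - set(CATEGORIES)
    if bad:
        raise ValueError(f"lexicon maps to unknown categories {sorted(bad)}")
    return frozenset(out)


def _category_predicate(
    category_filter: str | Callable[[PerceptDrawing], bool] | None,
) -> Callable[[PerceptDrawing], bool]:
    if category_filter is None:
        return lambda d: True
    if callable(category_filter):
        return category_filter
    name = category_filter.replace("_", "-")
    only = {
        "tactile-only": frozenset({"tactile"}),
        "proprioceptive-only": frozenset({"proprioceptive"}),
        "pain-only": frozenset({"painful"}),
    }
    if name == "all":
        return lambda d: True
    if name in only:
        target = only[name]
        return lambda d: d.categories == target
    raise ValueError(f"unknown category filter {category_filter!r}")


def cumulative_coverage(
    drawings: Sequence[PerceptDrawing],
    template: HandTemplate,
    category_filter: str | Callable[[PerceptDrawing], bool] | None = None,
) -> float:
    """Fraction of the hand covered by the union of (filtered) drawings.

    ``category_filter`` may be ``None``/``"all"``, one of ``"tactile-only"``,
    ``"proprioceptive-only"``, ``"pain-only"`` (exact category match, so a
    mixed tactile+proprioceptive percept is excluded from tactile-only), or
    an arbitrary predicate on drawings.
    """
    pred = _category_predicate(category_filter)
    union = np.zeros(template.mask.shape, dtype=bool)
    for d in drawings:
        if d.mask.shape != template.mask.shape:
            raise MaskShapeError(d.mask.shape, template.mask.shape)
        if pred(d):
            union |= d.mask
    union &= template.hand_region
    return float(union.sum()) / template.total_hand_area_px


def coverage_density(
    drawings: Sequence[PerceptDrawing], template: HandTemplate
) -> np.ndarray:
    """Per-pixel count of drawings covering each hand pixel.

    The figure-style density map: dividing by the number of tested contacts
    gives the percent of contacts evoking percepts at each pixel.
    """
    density = np.zeros(template.mask.shape, dtype=np.int64)
    for d in drawings:
        if d.mask.shape != template.mask.shape:
            raise MaskShapeError(d.mask.shape, template.mask.shape)
        density += d.mask & template.hand_region
    return density


def percept_area(
    drawing: PerceptDrawing, template: HandTemplate, units: str = "fraction"
) -> float:
    """Area of a single percept, as hand fraction or cm^2."""
    if drawing.mask.shape != template.mask.shape:
        raise MaskShapeError(drawing.mask.shape, template.mask.shape)
    npx = int((drawing.mask & template.hand_region).sum())
    if units == "fraction":
        return npx / template.total_hand_area_px
    if units == "cm2":
        return npx * template.cm_per_pixel**2
    raise ValueError(f"units must be 'fraction' or 'cm2', got {units!r}")


# ---------------------------------------------------------------------------
# External interfaces: PNG masks + JSON session manifests
# ---------------------------------------------------------------------------

def load_mask_png(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG as a boolean mask (nonzero = drawn)."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr > 0


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def load_session_manifest(
    manifest_path: str | Path,
    lexicon: Mapping[str, Iterable[str]] | None = None,
    *,
    unknown: str = "ignore",
) -> SessionRecord:
    """Read a JSON session manifest and its referenced PNG mask files.

    Manifest schema::

        {"system_id": ..., "session_id": ...,
         "drawings": [{"contact_id", "nerve", "file", "qualities": [...],
                       "electrode_id" (optional)}],
         "tested_contacts": [...]}

    Mask file paths are resolved relative to the manifest's directory.
    Categories are derived from qualities via :func:`categorize`.
    """
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    drawings = []
    for entry in spec["drawings"]:
        mask = load_mask_png(manifest_path.parent / entry["file"])
        qualities = frozenset(entry.get("qualities", []))
        drawings.append(
            PerceptDrawing(
                contact_id=entry["contact_id"],
                nerve=entry["nerve"],
                mask=mask,
                electrode_id=entry.get("electrode_id", ""),
                session_id=spec["session_id"],
                system_id=spec["system_id"],
                qualities=qualities,
                categories=categorize(qualities, lexicon, unknown=unknown),
            )
        )
    return SessionRecord(
        system_id=spec["system_id"],
        session_id=spec["session_id"],
        drawings=tuple(drawings),
        tested_contacts=tuple(spec["tested_contacts"]),
    )
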