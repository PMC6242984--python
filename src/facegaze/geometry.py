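"""Stimulus, screen and region-of-interest geometry.

Coordinates live in stimulus/screen pixel space: origin at the top-left
corner, x rightward, y downward, 0-based.  Region polygons are closed —
a point on the boundary belongs to the region.  Angular quantities are
small-angle per-pixel subtenses computed from the physical screen size
and the viewing distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "ScreenGeometry",
    "RegionOfInterest",
    "StimulusEntry",
    "MorphTimeline",
    "EXPRESSIONS",
    "ROI_LABELS",
    "ROI_PRIORITY",
    "morph_timeline",
    "stimulus_registry",
    "degrees_per_pixel",
    "build_default_rois",
    "assign_roi",
    "default_screen",
    "default_face_box",
]

#: The six basic facial expressions, in the canonical reporting order.
EXPRESSIONS = ("happiness", "surprise", "anger", "sadness", "disgust", "fear")

#: Face regions of interest used for fixation attribution.
ROI_LABELS = ("eyes", "nose", "mouth")

#: Tie-break priority when (misconfigured) regions overlap at a point.
ROI_PRIORITY = ("eyes", "mouth", "nose")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used for pixel <-> degree conversion.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    width_cm, height_cm
        Physical size of the displayed area in centimetres.
    viewing_distance_cm
        Eye-to-screen distance in centimetres.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")


@dataclass(frozen=True)
class RegionOfInterest:
    """A labelled polygonal face region in stimulus pixel coordinates."""

    label: str
    vertices: tuple[tuple[float, float], ...]
    polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("an ROI polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"ROI {self.label!r} polygon is degenerate "
                             "or self-intersecting")
        object.__setattr__(self, "polygon", poly)

    def contains(self, x: float, y: float) -> bool:
        """Closed point-in-polygon test (boundary counts as inside)."""
        return bool(shapely.intersects_xy(self.polygon, x, y))


@dataclass(frozen=True)
class StimulusEntry:
    """One dynamic stimulus: a model posing one expression."""

    model_id: int
    sex: str
    expression: str
    clip_duration_ms: float = 1033.0

    @property
    def stimulus_id(self) -> str:
        return f"M{self.model_id:02d}_{self.expression}"


@dataclass(frozen=True)
class MorphTimeline:
    """Frame timing of a neutral-to-apex morph clip."""

    n_frames: int
    frame_duration_ms: float
    onsets_ms: tuple[float, ...]
    total_ms: int


def morph_timeline(n_frames: int, fps: float) -> MorphTimeline:
    """Frame onsets and total duration of an ``n_frames`` clip at ``fps``.

    The total duration is the accumulated frame time rounded to the
    nearest millisecond, so 31 frames at 30 fps give a 1033-ms clip.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if fps <= 0:
        raise ValueError("fps must be positive")
    frame_ms = 1000.0 / fps
    onsets = tuple(i * frame_ms for i in range(n_frames))
    total = int(round(n_frames * frame_ms))
    return MorphTimeline(n_frames, frame_ms, onsets, total)


def stimulus_registry(
    n_models: int,
    expressions: Sequence[str] = EXPRESSIONS,
    clip_duration_ms: float = 1033.0,
) -> list[StimulusEntry]:
    """Full model x expression crossing, each pair exactly once.

    Models alternate female/male so that any even ``n_models`` gives a
    sex-balanced set.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    expressions = list(expressions)
    if not expressions:
        raise ValueError("expressions must be non-empty")
    if len(set(expressions)) != len(expressions):
        raise ValueError("expression labels must be unique")
    entries = []
    for m in range(1, n_models + 1):
        sex = "female" if m % 2 == 1 else "male"
        for expr in expressions:
            entries.append(StimulusEntry(m, sex, expr, clip_duration_ms))
    return entries


def degrees_per_pixel(screen: ScreenGeometry) -> tuple[float, float]:
    """Angular subtense of one pixel, horizontally and vertically.

    Small-angle per-pixel value: atan(pixel physical size / viewing
    distance), in degrees.  Horizontal and vertical values differ when
    pixels are not square.
    """
    ppcm_x = screen.width_cm / screen.width_px
    ppcm_y = screen.height_cm / screen.height_px
    d = screen.viewing_distance_cm
    return (math.degrees(math.atan(ppcm_x / d)),
            math.degrees(math.atan(ppcm_y / d)))


# Default band layout of the three regions within the face bounding box,
# as (x0, x1, y0, y1) fractions.  The eyes/brow band sits in the upper-
# middle face, the nose/cheek band in the middle, the mouth band in the
# lower face; the forehead (above the eyes band) and the chin (below the
# mouth band) stay uncovered.
DEFAULT_LAYOUT_FRACTIONS: Mapping[str, tuple[float, float, float, float]] = {
    "eyes": (0.08, 0.92, 0.22, 0.45),
    "nose": (0.18, 0.82, 0.45, 0.66),
    "mouth": (0.22, 0.78, 0.68, 0.88),
}


def build_default_rois(
    face_box: tuple[float, float, float, float],
    layout_fractions: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> tuple[RegionOfInterest, ...]:
    """Rectangular eyes / nose-cheek / mouth regions inside ``face_box``.

    Parameters
    ----------
    face_box
        ``(x0, y0, width, height)`` of the face bounding box in pixels.
    layout_fractions
        Per-label ``(x0, x1, y0, y1)`` fractions of the face box.  Bands
        must not overlap vertically; fractions must lie in [0, 1].
    """
    x0, y0, w, h = face_box
    if w <= 0 or h <= 0:
        raise ValueError("face_box must have positive width and height")
    fracs = dict(layout_fractions or DEFAULT_LAYOUT_FRACTIONS)
    missing = set(ROI_LABELS) - set(fracs)
    if missing:
        raise ValueError(f"layout_fractions missing labels: {sorted(missing)}")
    rois = []
    for label in ROI_LABELS:
        fx0, fx1, fy0, fy1 = fracs[label]
        for f in (fx0, fx1, fy0, fy1):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{label}: fractions must lie in [0, 1]")
        if fx1 <= fx0 or fy1 <= fy0:
            raise ValueError(f"{label}: degenerate band")
        ax0, ax1 = x0 + fx0 * w, x0 + fx1 * w
        ay0, ay1 = y0 + fy0 * h, y0 + fy1 * h
        rois.append(RegionOfInterest(
            label, ((ax0, ay0), (ax1, ay0), (ax1, ay1), (ax0, ay1))))
    bands = sorted((fracs[lab][2], fracs[lab][3], lab) for lab in ROI_LABELS)
    for (lo0, hi0, a), (lo1, hi1, b) in zip(bands, bands[1:]):
        if lo1 < hi0:
            raise ValueError(f"bands {a!r} and {b!r} overlap vertically")
    return tuple(rois)


def assign_roi(
    point: tuple[float, float],
    rois: Iterable[RegionOfInterest],
) -> str:
    """Label of the region containing ``point``; ``"other"`` if none.

    Boundaries are inclusive.  Should overlapping regions both contain
    the point, the fixed priority eyes > mouth > nose decides.
    """
    x, y = point
    hits = [r.label for r in rois if r.contains(x, y)]
    if not hits:
        return "other"
    if len(hits) == 1:
        return hits[0]
    for label in ROI_PRIORITY:
        if label in hits:
            return label
    return hits[0]


def assign_roi_batch(
    xs: np.ndarray,
    ys: np.ndarray,
    rois: Sequence[RegionOfInterest],
) -> np.ndarray:
    """Vectorised :func:`assign_roi` for arrays of coordinates."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    out = np.full(xs.shape, "other", dtype=object)
    # apply in reverse priority so higher-priority labels overwrite
    by_label = {r.label: r for r in rois}
    for label in reversed(ROI_PRIORITY):
        roi = by_label.get(label)
        if roi is None:
            continue
        mask = shapely.intersects_xy(roi.polygon, xs, ys)
        out[mask] = label
    return out


def default_screen() -> ScreenGeometry:
    """A 22-inch 1680x1050 display viewed from 80 cm.

    With this geometry one pixel subtends about 0.020 degrees in both
    directions, and the default face box below subtends 8.8 deg (width)
    x 11.6 deg (height) — the stimulus size the analysis defaults assume.
    """
    return ScreenGeometry(1680, 1050, 47.4, 29.6, 80.0)


def default_face_box(
    screen: ScreenGeometry | None = None,
    width_deg: float = 8.8,
    height_deg: float = 11.6,
) -> tuple[float, float, float, float]:
    """Centred face bounding box subtending the given visual angles."""
    screen = screen or default_screen()
    d = screen.viewing_distance_cm
    w_cm = 2.0 * d * math.tan(math.radians(width_deg / 2.0))
    h_cm = 2.0 * d * math.tan(math.radians(height_deg / 2.0))
    w_px = w_cm * screen.width_px / screen.width_cm
    h_px = h_cm * screen.height_px / screen.height_cm
    return ((screen.width_px - w_px) / 2.0, (screen.height_px - h_px) / 2.0,
            w_px, h_px)
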