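"""Bounding-box measurement core.

The box trainer is watched by two synchronized cameras.  The top camera
gives the in-plane position of each grasper tip (proxied by its detection
bounding-box centroid); the front camera gives its height.  Pixels map to
centimetres by plain per-axis scaling: each camera's frame spans a known
real-world extent, so ``px_per_cm = frame_px / real_cm`` per axis.  The
frame origin is the top-left corner, x rightward, y downward — hence a
*smaller* front-camera vertical coordinate means a physically *higher*
instrument.

The first fuzzy input is the Euclidean distance (cm) from the top-view
centroid to the centre of the field of interest; the second is the
front-view height coordinate (cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, ContractViolationError
from .fuzzy import LinguisticVariable

__all__ = [
    "BoundingBox",
    "CameraCalibration",
    "FieldOfInterest",
    "InstrumentObservation",
    "bbox_centroid",
    "px_per_cm",
    "to_cm",
    "to_px",
    "distance_to_field",
    "height_from_front",
    "classify_top_region",
    "classify_front_region",
]

CAMERAS = ("top", "front")
HANDS = ("right", "left")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, origin at the frame's top-left corner."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if min(self.xmin, self.ymin, self.xmax, self.ymax) < 0:
            raise ContractViolationError(f"negative bbox coordinate: {self}")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ContractViolationError(f"degenerate bbox: {self}")

    @property
    def centroid(self) -> tuple[float, float]:
        return bbox_centroid(self)


def bbox_centroid(b: BoundingBox) -> tuple[float, float]:
    """Centre of the box in pixels: ((xmin+xmax)/2, (ymin+ymax)/2)."""
    return 0.5 * (b.xmin + b.xmax), 0.5 * (b.ymin + b.ymax)


@dataclass(frozen=True)
class CameraCalibration:
    """Per-axis pixel <-> centimetre scaling for one camera."""

    frame_width_px: float
    frame_height_px: float
    real_width_cm: float
    real_height_cm: float

    def __post_init__(self) -> None:
        if min(
            self.frame_width_px,
            self.frame_height_px,
            self.real_width_cm,
            self.real_height_cm,
        ) <= 0:
            raise ConfigurationError(
                f"calibration extents must be strictly positive: {self}"
            )

    @property
    def px_per_cm_w(self) -> float:
        return self.frame_width_px / self.real_width_cm

    @property
    def px_per_cm_h(self) -> float:
        return self.frame_height_px / self.real_height_cm

    def to_cm(self, p_px: tuple[float, float]) -> tuple[float, float]:
        return p_px[0] / self.px_per_cm_w, p_px[1] / self.px_per_cm_h

    def to_px(self, p_cm: tuple[float, float]) -> tuple[float, float]:
        return p_cm[0] * self.px_per_cm_w, p_cm[1] * self.px_per_cm_h


def px_per_cm(c: CameraCalibration) -> tuple[float, float]:
    """Average pixels per centimetre, (width axis, height axis)."""
    return c.px_per_cm_w, c.px_per_cm_h


def to_cm(p_px: tuple[float, float], c: CameraCalibration) -> tuple[float, float]:
    """Convert a pixel point to centimetres, origin preserved at top-left."""
    return c.to_cm(p_px)


def to_px(p_cm: tuple[float, float], c: CameraCalibration) -> tuple[float, float]:
    return c.to_px(p_cm)


@dataclass(frozen=True)
class FieldOfInterest:
    """Centre of the field the hands should stay near (top view, cm) and
    the acceptable height band on the front view (cm, top-left origin)."""

    center_cm: tuple[float, float]
    front_band_cm: tuple[float, float]

    def __post_init__(self) -> None:
        h_low, h_high = self.front_band_cm
        if not h_low < h_high:
            raise ConfigurationError(
                f"front band must satisfy h_low < h_high: {self.front_band_cm}"
            )

    def validate_within(self, top: CameraCalibration) -> None:
        x, y = self.center_cm
        if not (0 <= x <= top.real_width_cm and 0 <= y <= top.real_height_cm):
            raise ConfigurationError(
                f"field centre {self.center_cm} outside top-camera extent "
                f"{top.real_width_cm} x {top.real_height_cm} cm"
            )


@dataclass(frozen=True)
class InstrumentObservation:
    """One grasper seen by one camera in one frame, in calibrated cm."""

    camera: str
    hand: str
    centroid_cm: tuple[float, float]
    score: float

    def __post_init__(self) -> None:
        if self.camera not in CAMERAS:
            raise ContractViolationError(f"unknown camera {self.camera!r}")
        if self.hand not in HANDS:
            raise ContractViolationError(f"unknown hand {self.hand!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ContractViolationError(f"score outside [0, 1]: {self.score}")


def distance_to_field(p_cm: tuple[float, float], f: FieldOfInterest) -> float:
    """Euclidean distance (cm) from a top-view point to the field centre."""
    return math.hypot(p_cm[0] - f.center_cm[0], p_cm[1] - f.center_cm[1])


def height_from_front(o: InstrumentObservation) -> float:
    """Vertical coordinate (cm) of a front-camera observation.

    Smaller values are physically higher (top-left origin).
    """
    if o.camera != "front":
        raise ContractViolationError(
            f"height_from_front needs a front-camera observation, got {o.camera!r}"
        )
    return o.centroid_cm[1]


def classify_top_region(dis: float, var: LinguisticVariable) -> str:
    """Crisp Close/Middle/Far label for reporting; the fuzzy path never
    hard-thresholds."""
    return var.best_label(dis)


def classify_front_region(h: float, var: LinguisticVariable) -> str:
    """Crisp High/Field/Down label for reporting (h = 0 is the frame top)."""
    return var.best_label(h)
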