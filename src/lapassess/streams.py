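"""Dual-camera stream fusion and session-level assessment.

The two cameras produce independent ordered detection streams.  Frames are
paired greedily by nearest timestamp within a tolerance (for two sorted
streams this two-pointer sweep attains the maximum number of pairs);
detections inside a frame are assigned to the right/left hand by class
label when the detector provides one, falling back to x-ordering; each
paired, assigned frame then runs through the cascaded supervisor.  The
result is a per-frame time series plus an aggregate summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .assessment import Assessor, FrameAssessment, HoldState
from .config import RunConfig
from .exceptions import ContractViolationError
from .geometry import BoundingBox, CameraCalibration, InstrumentObservation

__all__ = [
    "Detection",
    "DetectionRecord",
    "SessionResult",
    "pair_frames",
    "assign_hands",
    "run_session",
]

logger = logging.getLogger(__name__)

LETTERS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class Detection:
    """One detected object: class label, confidence, pixel bounding box."""

    label: str
    score: float
    bbox: BoundingBox

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ContractViolationError(f"score outside [0, 1]: {self.score}")


@dataclass(frozen=True)
class DetectionRecord:
    """All detections of one camera frame."""

    camera: str
    frame_index: int
    timestamp: float
    detections: tuple[Detection, ...] = ()

    def __post_init__(self) -> None:
        if self.camera not in ("top", "front"):
            raise ContractViolationError(f"unknown camera {self.camera!r}")
        if self.frame_index < 0:
            raise ContractViolationError(
                f"negative frame_index {self.frame_index}"
            )
        object.__setattr__(self, "detections", tuple(self.detections))


def validate_stream(records: Sequence[DetectionRecord]) -> None:
    """Check the within-stream ordering invariants."""
    for prev, cur in zip(records, records[1:]):
        if cur.frame_index <= prev.frame_index:
            raise ContractViolationError(
                f"frame_index not strictly increasing at {cur.frame_index}"
            )
        if cur.timestamp < prev.timestamp:
            raise ContractViolationError(
                f"timestamps decrease at frame {cur.frame_index}"
            )


def pair_frames(
    top_stream: Sequence[DetectionRecord],
    front_stream: Sequence[DetectionRecord],
    tolerance: float,
) -> tuple[list[tuple[DetectionRecord, DetectionRecord]], int, int]:
    """Greedy nearest-timestamp pairing of two sorted streams.

    Returns (pairs, unmatched_top, unmatched_front).  Each record is used
    at most once; records with no partner within ``tolerance`` seconds are
    counted, not assessed.
    """
    pairs: list[tuple[DetectionRecord, DetectionRecord]] = []
    i = j = 0
    while i < len(top_stream) and j < len(front_stream):
        dt = top_stream[i].timestamp - front_stream[j].timestamp
        if abs(dt) <= tolerance:
            pairs.append((top_stream[i], front_stream[j]))
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    unmatched_top = len(top_stream) - len(pairs)
    unmatched_front = len(front_stream) - len(pairs)
    return pairs, unmatched_top, unmatched_front


def _is_grasper(label: str) -> tuple[str | None, bool]:
    """(hand or None, looks-like-a-grasper) from a detector class label."""
    low = label.lower()
    if "grasper" not in low and "instrument" not in low and "tool" not in low:
        return None, False
    if "right" in low:
        return "right", True
    if "left" in low:
        return "left", True
    return None, True


def assign_hands(
    detections: Sequence[Detection],
    min_score: float,
    calibration: CameraCalibration,
    camera: str,
) -> tuple[InstrumentObservation | None, InstrumentObservation | None, list[str]]:
    """Assign a frame's detections to (right, left) observations.

    Detections below ``min_score`` are dropped.  Labelled right/left
    graspers win by highest score per class; unlabelled graspers fall back
    to x-ordering (rightmost centroid = right hand).  Surplus detections
    beyond one per hand are dropped with a flag.
    """
    flags: list[str] = []
    labelled: dict[str, list[Detection]] = {"right": [], "left": []}
    unlabelled: list[Detection] = []
    for det in detections:
        if det.score < min_score:
            continue
        hand, grasperish = _is_grasper(det.label)
        if not grasperish:
            continue
        if hand is None:
            unlabelled.append(det)
        else:
            labelled[hand].append(det)

    chosen: dict[str, Detection | None] = {"right": None, "left": None}
    for hand in ("right", "left"):
        cands = labelled[hand]
        if cands:
            if len(cands) > 1:
                flags.append(f"{camera}_duplicate_{hand}")
            chosen[hand] = max(cands, key=lambda d: d.score)

    if unlabelled:
        free = [h for h in ("right", "left") if chosen[h] is None]
        cands = sorted(unlabelled, key=lambda d: d.score, reverse=True)[: len(free)]
        if len(unlabelled) > len(free):
            flags.append(f"{camera}_surplus_detections")
        # Rightmost centroid becomes the right hand.
        cands.sort(key=lambda d: d.bbox.centroid[0], reverse=True)
        for hand, det in zip(free, cands):
            chosen[hand] = det

    def to_obs(hand: str) -> InstrumentObservation | None:
        det = chosen[hand]
        if det is None:
            return None
        return InstrumentObservation(
            camera, hand, calibration.to_cm(det.bbox.centroid), det.score
        )

    return to_obs("right"), to_obs("left"), flags


@dataclass
class SessionResult:
    """Per-frame assessment series plus aggregate summary."""

    series: pd.DataFrame
    summary: dict
    warnings: list[str] = field(default_factory=list)

    def plot(self, path=None):
        from .plotting import plot_session

        return plot_session(self, path)


_SERIES_COLUMNS = [
    "timestamp",
    "top_frame",
    "front_frame",
    "dis_right_cm",
    "height_right_cm",
    "dis_left_cm",
    "height_left_cm",
    "srhpa",
    "srhpa_letter",
    "slhpa",
    "slhpa_letter",
    "fpa",
    "fpa_letter",
    "flags",
]


def run_session(
    top_stream: Iterable[DetectionRecord],
    front_stream: Iterable[DetectionRecord],
    config: RunConfig,
    assessor: Assessor | None = None,
) -> SessionResult:
    """Pair, assign, assess every frame pair; deterministic for fixed inputs."""
    top = list(top_stream)
    front = list(front_stream)
    validate_stream(top)
    validate_stream(front)
    warnings: list[str] = []
    if not top or not front:
        warnings.append("empty_stream")

    assessor = assessor or Assessor.from_config(config)
    top_cal = config.cameras["top"].build()
    front_cal = config.cameras["front"].build()
    min_score = config.fusion.min_score

    pairs, unmatched_top, unmatched_front = pair_frames(
        top, front, config.fusion.pairing_tolerance_s
    )

    rows: list[dict] = []
    state = HoldState()
    n_assessed = 0
    n_skipped = 0
    hand_skips = {"right": 0, "left": 0}
    fpa_sum = 0.0
    fpa_min = None
    letter_counts = {letter: 0 for letter in LETTERS}

    for top_rec, front_rec in pairs:
        t_right, t_left, f1 = assign_hands(
            top_rec.detections, min_score, top_cal, "top"
        )
        fr_right, fr_left, f2 = assign_hands(
            front_rec.detections, min_score, front_cal, "front"
        )
        ts = 0.5 * (top_rec.timestamp + front_rec.timestamp)
        frame = assessor.assess_frame(
            t_right, t_left, fr_right, fr_left, state, timestamp=ts
        )
        flags = tuple(f1 + f2) + frame.flags
        rows.append(_frame_row(top_rec, front_rec, frame, flags))
        if frame.final is not None:
            n_assessed += 1
            fpa_sum += frame.final.crisp
            fpa_min = (
                frame.final.crisp
                if fpa_min is None
                else min(fpa_min, frame.final.crisp)
            )
            letter_counts[frame.final.letter] += 1
        else:
            n_skipped += 1
        for hand in ("right", "left"):
            if f"{hand}_skipped" in frame.flags:
                hand_skips[hand] += 1

    series = pd.DataFrame(rows, columns=_SERIES_COLUMNS)
    summary = {
        "frames_top": len(top),
        "frames_front": len(front),
        "frames_paired": len(pairs),
        "unmatched_top": unmatched_top,
        "unmatched_front": unmatched_front,
        "frames_assessed": n_assessed,
        "frames_skipped": n_skipped,
        "hand_skips": hand_skips,
        "mean_fpa": (fpa_sum / n_assessed) if n_assessed else None,
        "min_fpa": fpa_min,
        "letter_fractions": {
            letter: (count / n_assessed if n_assessed else 0.0)
            for letter, count in letter_counts.items()
        },
        "warnings": warnings,
    }
    logger.info(
        "session: %d top / %d front frames, %d paired, %d assessed, %d skipped",
        len(top),
        len(front),
        len(pairs),
        n_assessed,
        n_skipped,
    )
    return SessionResult(series, summary, warnings)


def _frame_row(
    top_rec: DetectionRecord,
    front_rec: DetectionRecord,
    frame: FrameAssessment,
    flags: tuple[str, ...],
) -> dict:
    def hand_fields(ha):
        if ha is None:
            return None, None, None, None
        return ha.dis_cm, ha.height_cm, ha.crisp, ha.letter

    dis_r, h_r, srhpa, srhpa_letter = hand_fields(frame.right)
    dis_l, h_l, slhpa, slhpa_letter = hand_fields(frame.left)
    return {
        "timestamp": frame.timestamp,
        "top_frame": top_rec.frame_index,
        "front_frame": front_rec.frame_index,
        "dis_right_cm": dis_r,
        "height_right_cm": h_r,
        "dis_left_cm": dis_l,
        "height_left_cm": h_l,
        "srhpa": srhpa,
        "srhpa_letter": srhpa_letter,
        "slhpa": slhpa,
        "slhpa_letter": slhpa_letter,
        "fpa": frame.final.crisp if frame.final else None,
        "fpa_letter": frame.final.letter if frame.final else None,
        "flags": ";".join(flags),
    }
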