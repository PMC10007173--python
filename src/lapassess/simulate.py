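"""Seeded synthetic dual-camera detection streams.

No videos are needed to exercise the pipeline: this module emulates what
the object detector would emit while a trainee of a given skill level works
the box trainer.  Each hand's tip follows a mean-reverting random walk
around a home position near the field centre, interrupted by a two-state
semi-Markov excursion process — entering, with a per-frame probability, a
*Far* excursion (drifting out of the field in the top view) or a *High*
excursion (lifting toward the top camera), each held for a geometrically
distributed dwell.  While a hand sits in the High band it disappears from
the front camera with a stated occlusion probability, reproducing the
situation where an instrument is so close to the top camera that the front
camera cannot see it.

Positions are projected to both cameras through the configured calibration
and emitted as bounding boxes with detection noise (centroid jitter,
confidence scores, false negatives).  A ground-truth sidecar carries the
true per-frame distance/height, the excursion state and the occlusion
flags, so oracle tests can check the assessor against what was simulated.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import RunConfig, build_variable, default_config
from .exceptions import ConfigurationError
from .geometry import BoundingBox
from .streams import Detection, DetectionRecord

__all__ = [
    "HandKinematics",
    "SkillProfile",
    "SimulatedSession",
    "EXPERT",
    "INTERMEDIATE",
    "NOVICE",
    "get_profile",
    "simulate_session",
    "stationary_excursion_occupancy",
    "high_band_threshold",
    "packaged_fixtures",
    "FIXTURE_SPECS",
]


@dataclass(frozen=True)
class HandKinematics:
    """Stationary behaviour of one hand, in cm."""

    home_offset_cm: tuple[float, float]  # from the field centre, top view
    height_mean_cm: float
    jitter_cm: float  # per-frame Gaussian step scale
    revert_rate: float  # pull toward the target per frame, in (0, 1]


@dataclass(frozen=True)
class SkillProfile:
    """Everything that differs between expert and novice sessions."""

    name: str
    right: HandKinematics
    left: HandKinematics
    excursion_prob: float  # per-frame probability of starting an excursion
    excursion_dwell_frames: float  # mean dwell; exit prob = 1/dwell per frame
    far_offset_cm: float  # radial target of a Far excursion
    high_height_cm: float  # height target of a High excursion
    occlusion_prob: float  # front-camera drop prob while in the High band
    centroid_jitter_px: float
    score_range: tuple[float, float]
    false_negative_rate: float
    box_w_px: float = 120.0
    box_h_px: float = 60.0
    box_jitter: float = 0.1

    def __post_init__(self) -> None:
        for p in (
            self.excursion_prob,
            self.occlusion_prob,
            self.false_negative_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability outside [0, 1]: {p}")
        if self.excursion_dwell_frames < 1:
            raise ConfigurationError("excursion dwell must be >= 1 frame")
        if min(self.centroid_jitter_px, self.box_jitter, self.far_offset_cm) < 0:
            raise ConfigurationError("scales must be non-negative")


EXPERT = SkillProfile(
    name="expert",
    right=HandKinematics((2.5, 1.0), 11.25, 0.35, 0.15),
    left=HandKinematics((-2.5, 1.0), 11.25, 0.35, 0.15),
    excursion_prob=0.005,
    excursion_dwell_frames=10.0,
    far_offset_cm=16.0,
    high_height_cm=1.5,
    occlusion_prob=0.9,
    centroid_jitter_px=2.0,
    score_range=(0.80, 0.99),
    false_negative_rate=0.01,
)

INTERMEDIATE = SkillProfile(
    name="intermediate",
    right=HandKinematics((5.0, 1.5), 11.25, 0.8, 0.15),
    left=HandKinematics((-5.0, 1.5), 11.25, 0.8, 0.15),
    excursion_prob=0.015,
    excursion_dwell_frames=12.0,
    far_offset_cm=16.0,
    high_height_cm=1.5,
    occlusion_prob=0.85,
    centroid_jitter_px=3.0,
    score_range=(0.70, 0.97),
    false_negative_rate=0.03,
)

NOVICE = SkillProfile(
    name="novice",
    right=HandKinematics((8.0, 2.0), 11.25, 1.5, 0.12),
    left=HandKinematics((-8.0, 2.0), 11.25, 1.5, 0.12),
    excursion_prob=0.03,
    excursion_dwell_frames=15.0,
    far_offset_cm=18.0,
    high_height_cm=1.5,
    occlusion_prob=0.85,
    centroid_jitter_px=4.0,
    score_range=(0.65, 0.95),
    false_negative_rate=0.05,
)

_PROFILES = {p.name: p for p in (EXPERT, INTERMEDIATE, NOVICE)}


def get_profile(name: str) -> SkillProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown profile {name!r}; choose from {sorted(_PROFILES)}"
        ) from None


def stationary_excursion_occupancy(profile: SkillProfile) -> float:
    """Long-run fraction of frames a hand spends in an excursion.

    The excursion switch is a two-state Markov chain with entry probability
    ``p`` and exit probability ``q = 1 / dwell``; its stationary occupancy
    is ``p / (p + q)``.
    """
    p = profile.excursion_prob
    q = 1.0 / profile.excursion_dwell_frames
    return p / (p + q)


def high_band_threshold(config: RunConfig) -> float:
    """Largest height (cm) still classified High — the front-occlusion band."""
    var = build_variable(config.variables["height"])
    lo, hi = var.universe
    grid = np.linspace(lo, hi, 2001)
    in_high = [x for x in grid if var.best_label(float(x)) == "High"]
    return float(max(in_high)) if in_high else lo


@dataclass
class SimulatedSession:
    top: list[DetectionRecord]
    front: list[DetectionRecord]
    truth: list[dict]


@dataclass
class _HandState:
    pos: np.ndarray  # (x, y) cm on the top plane
    h: float  # cm on the front vertical axis
    state: str = "nominal"  # nominal | far | high
    far_target: np.ndarray | None = None


def _shift_into_frame(
    xmin: float, ymin: float, xmax: float, ymax: float, w: float, h: float
) -> BoundingBox:
    if xmin < 0:
        xmax, xmin = xmax - xmin, 0.0
    elif xmax > w:
        xmin, xmax = xmin - (xmax - w), w
    if ymin < 0:
        ymax, ymin = ymax - ymin, 0.0
    elif ymax > h:
        ymin, ymax = ymin - (ymax - h), h
    return BoundingBox(
        round(max(xmin, 0.0), 1),
        round(max(ymin, 0.0), 1),
        round(min(xmax, w), 1),
        round(min(ymax, h), 1),
    )


def simulate_session(
    profile: SkillProfile,
    n_frames: int = 600,
    fps: float = 30.0,
    seed: int = 0,
    config: RunConfig | None = None,
) -> SimulatedSession:
    """Generate paired top/front detection streams plus a truth sidecar.

    Deterministic for a fixed ``(profile, n_frames, fps, seed, config)``.
    """
    if n_frames <= 0 or fps <= 0:
        raise ConfigurationError("n_frames and fps must be positive")
    cfg = config or default_config()
    rng = np.random.default_rng(seed)
    top_cal = cfg.cameras["top"].build()
    front_cal = cfg.cameras["front"].build()
    center = np.asarray(cfg.field.center_cm, dtype=float)
    band_mid = 0.5 * sum(cfg.field.front_band_cm)
    high_thresh = high_band_threshold(cfg)
    exit_prob = 1.0 / profile.excursion_dwell_frames

    kin = {"right": profile.right, "left": profile.left}
    hands = {
        hand: _HandState(
            pos=center + np.asarray(k.home_offset_cm), h=k.height_mean_cm
        )
        for hand, k in kin.items()
    }

    top_stream: list[DetectionRecord] = []
    front_stream: list[DetectionRecord] = []
    truth: list[dict] = []

    for i in range(n_frames):
        t = round(i / fps, 4)
        top_dets: list[Detection] = []
        front_dets: list[Detection] = []
        frame_truth: dict = {"frame": i, "timestamp": t}

        for hand in ("right", "left"):
            k = kin[hand]
            st = hands[hand]

            # excursion switch
            if st.state == "nominal":
                if rng.random() < profile.excursion_prob:
                    if rng.random() < 0.5:
                        st.state = "far"
                        side = 1.0 if hand == "right" else -1.0
                        angle = rng.uniform(-0.3, 0.3)
                        st.far_target = center + profile.far_offset_cm * np.array(
                            [side * np.cos(angle), np.sin(angle)]
                        )
                    else:
                        st.state = "high"
            elif rng.random() < exit_prob:
                st.state = "nominal"
                st.far_target = None

            # targets for the mean-reverting walk
            if st.state == "far":
                pos_target = st.far_target
                h_target = k.height_mean_cm
            elif st.state == "high":
                pos_target = center + np.asarray(k.home_offset_cm)
                h_target = profile.high_height_cm
            else:
                pos_target = center + np.asarray(k.home_offset_cm)
                h_target = k.height_mean_cm

            st.pos = (
                st.pos
                + k.revert_rate * (pos_target - st.pos)
                + k.jitter_cm * rng.standard_normal(2)
            )
            st.h = (
                st.h
                + k.revert_rate * (h_target - st.h)
                + k.jitter_cm * rng.standard_normal()
            )
            st.pos[0] = float(np.clip(st.pos[0], 0.5, top_cal.real_width_cm - 0.5))
            st.pos[1] = float(np.clip(st.pos[1], 0.5, top_cal.real_height_cm - 0.5))
            st.h = float(np.clip(st.h, 0.3, front_cal.real_height_cm - 0.5))

            dis = float(np.linalg.norm(st.pos - center))
            in_high_band = st.h <= high_thresh
            occluded = bool(in_high_band and rng.random() < profile.occlusion_prob)
            top_fn = rng.random() < profile.false_negative_rate
            front_fn = rng.random() < profile.false_negative_rate
            top_detected = not top_fn
            front_detected = not (occluded or front_fn)

            # box size grows as the instrument rises toward the top camera
            scale = 1.0 + 0.6 * max(0.0, (band_mid - st.h) / band_mid)
            size_jit = 1.0 + (
                rng.uniform(-profile.box_jitter, profile.box_jitter)
                if profile.box_jitter > 0
                else 0.0
            )
            bw = profile.box_w_px * scale * size_jit
            bh = profile.box_h_px * scale * size_jit

            if top_detected:
                cx, cy = top_cal.to_px((st.pos[0], st.pos[1]))
                cx += profile.centroid_jitter_px * rng.standard_normal()
                cy += profile.centroid_jitter_px * rng.standard_normal()
                bbox = _shift_into_frame(
                    cx - bw / 2,
                    cy - bh / 2,
                    cx + bw / 2,
                    cy + bh / 2,
                    top_cal.frame_width_px,
                    top_cal.frame_height_px,
                )
                score = round(float(rng.uniform(*profile.score_range)), 3)
                top_dets.append(Detection(f"{hand}_grasper", score, bbox))
            if front_detected:
                cx, cy = front_cal.to_px((st.pos[0], st.h))
                cx += profile.centroid_jitter_px * rng.standard_normal()
                cy += profile.centroid_jitter_px * rng.standard_normal()
                bbox = _shift_into_frame(
                    cx - bw / 2,
                    cy - bh / 2,
                    cx + bw / 2,
                    cy + bh / 2,
                    front_cal.frame_width_px,
                    front_cal.frame_height_px,
                )
                score = round(float(rng.uniform(*profile.score_range)), 3)
                front_dets.append(Detection(f"{hand}_grasper", score, bbox))

            frame_truth[hand] = {
                "dis_cm": round(dis, 4),
                "height_cm": round(st.h, 4),
                "state": st.state,
                "in_high_band": in_high_band,
                "occluded": occluded,
                "top_detected": top_detected,
                "front_detected": front_detected,
            }

        top_stream.append(DetectionRecord("top", i, t, tuple(top_dets)))
        front_stream.append(DetectionRecord("front", i, t, tuple(front_dets)))
        truth.append(frame_truth)

    return SimulatedSession(top_stream, front_stream, truth)


def noiseless(profile: SkillProfile) -> SkillProfile:
    """Degenerate copy: no jitter, no excursions, no detection noise."""
    return replace(
        profile,
        right=replace(profile.right, jitter_cm=0.0),
        left=replace(profile.left, jitter_cm=0.0),
        excursion_prob=0.0,
        centroid_jitter_px=0.0,
        false_negative_rate=0.0,
        box_jitter=0.0,
        score_range=(0.9, 0.9),
    )


# -- packaged fixtures -----------------------------------------------------

#: Seeds and sizes of the fixture streams shipped under data/fixtures.
FIXTURE_SPECS: dict[str, dict] = {
    "expert": {"seed": 101, "n_frames": 80, "fps": 30.0},
    "novice": {"seed": 202, "n_frames": 80, "fps": 30.0},
}


def packaged_fixtures() -> dict[str, dict[str, Path]]:
    """Paths of the shipped fixture streams, truth sidecars and summaries."""
    root = importlib.resources.files("lapassess").joinpath("data/fixtures")
    out: dict[str, dict[str, Path]] = {}
    for name in FIXTURE_SPECS:
        out[name] = {
            "top": Path(str(root.joinpath(f"{name}_top.jsonl"))),
            "front": Path(str(root.joinpath(f"{name}_front.jsonl"))),
            "truth": Path(str(root.joinpath(f"{name}_truth.jsonl"))),
            "summary": Path(str(root.joinpath(f"{name}_summary.json"))),
        }
    return out


def generate_fixture_files(outdir: str | Path) -> None:
    """Regenerate the packaged fixtures (documented seeds in FIXTURE_SPECS)."""
    from .io import write_detection_stream, write_summary_json, write_truth_sidecar
    from .streams import run_session

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    for name, spec in FIXTURE_SPECS.items():
        sess = simulate_session(
            get_profile(name), spec["n_frames"], spec["fps"], spec["seed"], cfg
        )
        write_detection_stream(sess.top, outdir / f"{name}_top.jsonl")
        write_detection_stream(sess.front, outdir / f"{name}_front.jsonl")
        write_truth_sidecar(sess.truth, outdir / f"{name}_truth.jsonl")
        result = run_session(sess.top, sess.front, cfg)
        write_summary_json(result, outdir / f"{name}_summary.json")
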