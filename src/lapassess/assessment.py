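"""The cascaded fuzzy supervisor.

Two identical first-level MISO systems grade the right and left hand from
(distance-to-field, height): singleton fuzzification, nine rules, centroid
defuzzification to a percent plus a letter (SRHPA / SLHPA).  Each crisp
score is then *refuzzified* on a coarser Excellent/Good/Bad variable, and a
second-level system combines the two refuzzified profiles into the final
performance assessment (FPA).

Missing detections follow the published semantics: a hand absent from the
front camera while present in the top view is so close to the top camera
that it must be in the High region — its height is substituted with the
High-label prototype.  A hand absent from the top view keeps its last known
distance for a bounded hold window; beyond that the hand (and with it the
final grade) is flag-skipped for the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .config import (
    RunConfig,
    build_first_level,
    build_second_level,
    build_variable,
)
from .fuzzy import LinguisticVariable, MamdaniSystem, grade_letter
from .geometry import (
    FieldOfInterest,
    InstrumentObservation,
    distance_to_field,
    height_from_front,
)

__all__ = [
    "HandAssessment",
    "RefuzzifiedScore",
    "FinalAssessment",
    "FrameAssessment",
    "HoldState",
    "Assessor",
]

HANDS = ("right", "left")


@dataclass(frozen=True)
class HandAssessment:
    """First-level output for one hand: crisp percent plus letter grade."""

    hand: str
    crisp: float
    letter: str
    dis_cm: float
    height_cm: float


@dataclass(frozen=True)
class RefuzzifiedScore:
    """Excellent/Good/Bad membership profile of a first-level crisp score."""

    degrees: dict[str, float]


@dataclass(frozen=True)
class FinalAssessment:
    crisp: float
    letter: str
    right: HandAssessment | None = None
    left: HandAssessment | None = None


@dataclass(frozen=True)
class FrameAssessment:
    """Per-frame cascade output; any part may be missing, with flags saying why."""

    timestamp: float
    right: HandAssessment | None
    left: HandAssessment | None
    final: FinalAssessment | None
    flags: tuple[str, ...] = ()


@dataclass
class _HandHold:
    last_dis: float | None = None
    age: int = 0  # frames since the top camera last saw the hand


@dataclass
class HoldState:
    """Mutable per-session memory for the missing-top-view hold policy."""

    right: _HandHold = field(default_factory=_HandHold)
    left: _HandHold = field(default_factory=_HandHold)

    def for_hand(self, hand: str) -> _HandHold:
        return self.right if hand == "right" else self.left


class Assessor:
    """Builds and runs the full cascade for one configuration."""

    def __init__(
        self,
        first_level: MamdaniSystem,
        refuzz_var: LinguisticVariable,
        second_level: MamdaniSystem,
        fieldofinterest: FieldOfInterest,
        hold_frames: int = 15,
    ) -> None:
        self.first_level = first_level
        self.refuzz_var = refuzz_var
        self.second_level = second_level
        self.field = fieldofinterest
        self.hold_frames = int(hold_frames)
        self.dist_var = first_level.inputs[0]
        self.height_var = first_level.inputs[1]
        # Height substituted when the front camera misses a hand: the
        # prototype (peak) of the High label.
        self.high_prototype = self.height_var.labels["High"].peak

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "Assessor":
        return cls(
            first_level=build_first_level(cfg),
            refuzz_var=build_variable(cfg.variables["refuzzified"]),
            second_level=build_second_level(cfg),
            fieldofinterest=cfg.field.build(),
            hold_frames=cfg.fusion.hold_frames,
        )

    # -- first level -------------------------------------------------------

    def assess_hand(self, dis: float, h: float, hand: str) -> HandAssessment:
        """Grade one hand from its distance and height (cm).

        Both hands use the identical variables and rule base, so the
        assessment is symmetric by construction.
        """
        if hand not in HANDS:
            raise ValueError(f"unknown hand {hand!r}")
        crisp, letter = self.first_level.evaluate(
            {self.dist_var.name: dis, self.height_var.name: h}
        )
        return HandAssessment(hand, crisp, letter, dis, h)

    def refuzzify(self, score: HandAssessment | float) -> RefuzzifiedScore:
        """Singleton-fuzzify a first-level crisp percent on the coarse
        Excellent/Good/Bad variable used by the second level."""
        crisp = score.crisp if isinstance(score, HandAssessment) else float(score)
        return RefuzzifiedScore(self.refuzz_var.fuzzify(crisp))

    # -- second level ------------------------------------------------------

    def assess_final(
        self,
        right: RefuzzifiedScore,
        left: RefuzzifiedScore,
        right_hand: HandAssessment | None = None,
        left_hand: HandAssessment | None = None,
    ) -> FinalAssessment:
        """Combine the two refuzzified hand profiles into the final grade.

        The right hand feeds the rule table's rows, the left its columns;
        the published table is asymmetric, so the order matters.
        """
        fuzzified: Mapping[str, Mapping[str, float]] = {
            "SRHPAr": right.degrees,
            "SLHPAr": left.degrees,
        }
        activations = self.second_level.evaluate_rules(fuzzified)
        crisp = self.second_level.defuzzify(activations)
        letter = grade_letter(self.second_level.output, crisp)
        return FinalAssessment(crisp, letter, right_hand, left_hand)

    def assess_pair(self, right: HandAssessment, left: HandAssessment) -> FinalAssessment:
        return self.assess_final(
            self.refuzzify(right), self.refuzzify(left), right, left
        )

    # -- per-frame cascade -------------------------------------------------

    def assess_frame(
        self,
        top_right: InstrumentObservation | None,
        top_left: InstrumentObservation | None,
        front_right: InstrumentObservation | None,
        front_left: InstrumentObservation | None,
        state: HoldState,
        timestamp: float = 0.0,
    ) -> FrameAssessment:
        """Run the full cascade on one paired frame.

        Missing-detection policy, per hand:

        * front missing, distance known — height := High prototype
          (flag ``<hand>_front_high``);
        * top missing — reuse the last known distance for up to
          ``hold_frames`` frames (flag ``<hand>_top_hold``), else the hand
          is skipped (flag ``<hand>_skipped``);
        * either hand skipped — no final grade (flag ``final_skipped``).
        """
        flags: list[str] = []
        hands: dict[str, HandAssessment | None] = {}
        obs = {
            "right": (top_right, front_right),
            "left": (top_left, front_left),
        }
        for hand, (top_obs, front_obs) in obs.items():
            hold = state.for_hand(hand)
            if top_obs is not None:
                dis = distance_to_field(top_obs.centroid_cm, self.field)
                hold.last_dis = dis
                hold.age = 0
            else:
                hold.age += 1
                if hold.last_dis is not None and hold.age <= self.hold_frames:
                    dis = hold.last_dis
                    flags.append(f"{hand}_top_hold")
                else:
                    flags.append(f"{hand}_skipped")
                    hands[hand] = None
                    continue
            if front_obs is not None:
                h = height_from_front(front_obs)
            else:
                h = self.high_prototype
                flags.append(f"{hand}_front_high")
            hands[hand] = self.assess_hand(dis, h, hand)

        right, left = hands["right"], hands["left"]
        if right is not None and left is not None:
            final = self.assess_pair(right, left)
        else:
            final = None
            flags.append("final_skipped")
        return FrameAssessment(timestamp, right, left, final, tuple(flags))

    # -- introspection -----------------------------------------------------

    def explain(self, dis: float, h: float) -> dict:
        """Full trace of one first-level evaluation, for debugging/CLI."""
        fuzzified = self.first_level.fuzzify(
            {self.dist_var.name: dis, self.height_var.name: h}
        )
        activations = self.first_level.evaluate_rules(fuzzified)
        crisp = self.first_level.defuzzify(activations)
        fired = []
        for rule in self.first_level.rules:
            strength = min(
                fuzzified[var][label] for var, label in rule.antecedent.items()
            )
            if strength > 0:
                fired.append(
                    {
                        "antecedent": dict(rule.antecedent),
                        "consequent": rule.consequent,
                        "strength": strength,
                    }
                )
        return {
            "inputs": {self.dist_var.name: dis, self.height_var.name: h},
            "fuzzified": fuzzified,
            "fired_rules": fired,
            "activations": activations,
            "crisp": crisp,
            "letter": grade_letter(self.first_level.output, crisp),
        }
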