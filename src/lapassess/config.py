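"""Run configuration: schema, defaults, loading and serialization.

One YAML document governs everything — camera calibration, field geometry,
both fuzzy levels' linguistic variables and rule tables, and the stream
fusion policy.  There are no hidden constants in code: the packaged
``data/default_config.yaml`` is the single source of defaults and encodes
the published supervisor.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .exceptions import ConfigurationError
from .fuzzy import FuzzyRule, LinguisticVariable, MamdaniSystem, MembershipFunction
from .geometry import CameraCalibration, FieldOfInterest

__all__ = [
    "RunConfig",
    "default_config",
    "load_config",
    "config_to_yaml",
    "build_variable",
    "build_first_level",
    "build_second_level",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraConfig(_Strict):
    frame_width_px: float = Field(gt=0)
    frame_height_px: float = Field(gt=0)
    real_width_cm: float = Field(gt=0)
    real_height_cm: float = Field(gt=0)

    def build(self) -> CameraCalibration:
        return CameraCalibration(
            self.frame_width_px,
            self.frame_height_px,
            self.real_width_cm,
            self.real_height_cm,
        )


class FieldConfig(_Strict):
    center_cm: tuple[float, float]
    front_band_cm: tuple[float, float]

    def build(self) -> FieldOfInterest:
        return FieldOfInterest(tuple(self.center_cm), tuple(self.front_band_cm))


class MFConfig(_Strict):
    shape: Literal["triangular", "trapezoidal"]
    breakpoints: list[float]


class VariableConfig(_Strict):
    name: str
    universe: tuple[float, float]
    labels: dict[str, MFConfig]


class RulesConfig(_Strict):
    first_level: dict[str, dict[str, str]]
    second_level: dict[str, dict[str, str]]
    symmetrize_second_level: bool = False


class FusionConfig(_Strict):
    pairing_tolerance_s: float = Field(default=0.02, gt=0)
    min_score: float = Field(default=0.5, ge=0, le=1)
    hold_frames: int = Field(default=15, ge=0)


_REQUIRED_VARIABLES = (
    "distance",
    "height",
    "hand_score",
    "refuzzified",
    "final_score",
)


class RunConfig(_Strict):
    """Validated top-level configuration document."""

    cameras: dict[Literal["top", "front"], CameraConfig]
    field: FieldConfig
    variables: dict[str, VariableConfig]
    rules: RulesConfig
    defuzzification: Literal["center_of_average", "center_of_gravity"] = (
        "center_of_average"
    )
    fusion: FusionConfig = FusionConfig()

    @model_validator(mode="after")
    def _check_structure(self) -> "RunConfig":
        for cam in ("top", "front"):
            if cam not in self.cameras:
                raise ValueError(f"cameras.{cam} is required")
        missing = [v for v in _REQUIRED_VARIABLES if v not in self.variables]
        if missing:
            raise ValueError(f"variables missing: {missing}")
        return self


def build_variable(vc: VariableConfig, name: str | None = None) -> LinguisticVariable:
    labels = {
        label: MembershipFunction(mf.shape, tuple(mf.breakpoints))
        for label, mf in vc.labels.items()
    }
    return LinguisticVariable(name or vc.name, tuple(vc.universe), labels)


def _rules_from_table(
    table: dict[str, dict[str, str]],
    row_var: str,
    col_var: str,
) -> tuple[FuzzyRule, ...]:
    rules = []
    for row_label, cells in table.items():
        for col_label, consequent in cells.items():
            rules.append(
                FuzzyRule({row_var: row_label, col_var: col_label}, consequent)
            )
    return tuple(rules)


def build_first_level(cfg: RunConfig) -> MamdaniSystem:
    """The per-hand MISO system: (distance, height) -> letter-graded percent.

    Identical for both hands; rule table rows are height labels, columns
    distance labels.
    """
    dist = build_variable(cfg.variables["distance"])
    height = build_variable(cfg.variables["height"])
    out = build_variable(cfg.variables["hand_score"])
    rules = _rules_from_table(cfg.rules.first_level, height.name, dist.name)
    try:
        return MamdaniSystem((dist, height), out, rules, cfg.defuzzification)
    except ConfigurationError as exc:
        raise ConfigurationError(f"rules.first_level: {exc}") from exc


def _symmetrized(table: dict[str, dict[str, str]]) -> dict[str, dict[str, str]]:
    out = {r: dict(c) for r, c in table.items()}
    out["Good"]["Bad"] = "D"
    out["Bad"]["Good"] = "D"
    return out


def build_second_level(cfg: RunConfig) -> MamdaniSystem:
    """The cascade head: (SRHPAr, SLHPAr) -> final performance assessment.

    Rows of the rule table are the right hand, columns the left hand; the
    table is asymmetric as published unless ``symmetrize_second_level``.
    """
    base = cfg.variables["refuzzified"]
    right = build_variable(base, "SRHPAr")
    left = build_variable(base, "SLHPAr")
    out = build_variable(cfg.variables["final_score"])
    table = cfg.rules.second_level
    if cfg.rules.symmetrize_second_level:
        table = _symmetrized(table)
    rules = _rules_from_table(table, "SRHPAr", "SLHPAr")
    try:
        return MamdaniSystem((right, left), out, rules, cfg.defuzzification)
    except ConfigurationError as exc:
        raise ConfigurationError(f"rules.second_level: {exc}") from exc


def _validate_buildable(cfg: RunConfig) -> RunConfig:
    """Fail fast on semantic errors (bad breakpoints, incomplete rules...)."""
    build_first_level(cfg)
    build_second_level(cfg)
    build_variable(cfg.variables["refuzzified"])
    cfg.field.build().validate_within(cfg.cameras["top"].build())
    return cfg


def default_config() -> RunConfig:
    """The packaged configuration encoding the published supervisor."""
    text = (
        importlib.resources.files("lapassess")
        .joinpath("data/default_config.yaml")
        .read_text(encoding="utf-8")
    )
    return parse_config(yaml.safe_load(text))


def parse_config(document: dict) -> RunConfig:
    try:
        cfg = RunConfig.model_validate(document)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration: {locs}") from exc
    return _validate_buildable(cfg)


def load_config(path: str | Path) -> RunConfig:
    """Parse and fully validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        document = yaml.safe_load(fh)
    if not isinstance(document, dict):
        raise ConfigurationError(f"{path}: not a mapping document")
    return parse_config(document)


def config_to_yaml(cfg: RunConfig) -> str:
    """Serialize; ``parse_config(yaml.safe_load(...))`` round-trips."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)
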