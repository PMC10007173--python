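"""Generic Mamdani fuzzy inference.

The assessment supervisor is built from classical Mamdani machinery:
piecewise-linear (triangular / trapezoidal) membership functions, singleton
fuzzification of crisp measurements, min-conjunction / max-aggregation rule
evaluation, and two defuzzifiers:

* ``center_of_average`` — the activation-weighted mean of each activated
  label's representative point (triangle peak, trapezoid plateau midpoint).
  This is the discrete weighted-sum centroid and the package default.
* ``center_of_gravity`` — the centroid of the max-aggregated, min-clipped
  output surface.  Because every membership function here is piecewise
  linear, the clipped-and-aggregated surface is piecewise linear too, and
  the centroid is computed exactly by enumerating every kink (breakpoints,
  clip crossings, pairwise crossings) and integrating segment by segment.

Nothing in this module knows about cameras or graspers; it is reused for
both cascade levels and is configurable through :mod:`lapassess.config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .exceptions import (
    ConfigurationError,
    ContractViolationError,
    NoRuleFiredError,
)

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "MamdaniSystem",
    "membership_degree",
    "fuzzify_singleton",
    "evaluate_rules",
    "defuzzify",
    "grade_letter",
]

DEFUZZ_METHODS = ("center_of_average", "center_of_gravity")


@dataclass(frozen=True)
class MembershipFunction:
    """A triangular or trapezoidal membership function.

    Breakpoints are abscissae in the units of the owning variable's
    universe: 3 for a triangle ``(a, b, c)`` peaked at ``b``, 4 for a
    trapezoid ``(a, b, c, d)`` with plateau ``[b, c]``.  Repeated
    breakpoints give shouldered (one-sided) shapes, e.g. ``(0, 0, 12)`` is
    a left shoulder with full membership at 0.
    """

    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in ("triangular", "trapezoidal"):
            raise ConfigurationError(f"unknown MF shape {self.shape!r}")
        n = 3 if self.shape == "triangular" else 4
        bp = tuple(float(b) for b in self.breakpoints)
        if len(bp) != n:
            raise ConfigurationError(
                f"{self.shape} MF needs {n} breakpoints, got {len(bp)}"
            )
        if any(not math.isfinite(b) for b in bp):
            raise ConfigurationError(f"non-finite breakpoint in {bp}")
        if any(b2 < b1 for b1, b2 in zip(bp, bp[1:])):
            raise ConfigurationError(f"breakpoints must be non-decreasing: {bp}")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def support(self) -> tuple[float, float]:
        return self.breakpoints[0], self.breakpoints[-1]

    @property
    def peak(self) -> float:
        """Representative point: triangle peak, or trapezoid plateau midpoint."""
        if self.shape == "triangular":
            return self.breakpoints[1]
        return 0.5 * (self.breakpoints[1] + self.breakpoints[2])

    def __call__(self, x: float) -> float:
        if not math.isfinite(x):
            raise ContractViolationError(f"membership degree of non-finite x={x}")
        if self.shape == "triangular":
            a, b, c = self.breakpoints
            lo, hi = b, b
        else:
            a, b, c, d = self.breakpoints
            lo, hi = b, c
            c = d
        if x < a or x > c:
            return 0.0
        if lo <= x <= hi:
            return 1.0
        if x < lo:  # rising edge; lo > a here, so no zero division
            return (x - a) / (lo - a)
        return (c - x) / (c - hi)


def membership_degree(mf: MembershipFunction, x: float) -> float:
    """Piecewise-linear membership degree of ``x`` under ``mf``, in [0, 1]."""
    return mf(x)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable over a closed universe with ordered, labelled MFs.

    For graded output variables the labels are declared best-first
    (A, B, ... E); ties in :func:`grade_letter` resolve to the later — i.e.
    worse — label, erring against the trainee.
    """

    name: str
    universe: tuple[float, float]
    labels: dict[str, MembershipFunction]

    _COMPLETENESS_GRID = 1001

    def __post_init__(self) -> None:
        lo, hi = (float(v) for v in self.universe)
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
            raise ConfigurationError(
                f"variable {self.name!r}: universe must be a finite [lo, hi] "
                f"with lo < hi, got {self.universe}"
            )
        object.__setattr__(self, "universe", (lo, hi))
        if not self.labels:
            raise ConfigurationError(f"variable {self.name!r} has no labels")
        for label, mf in self.labels.items():
            s_lo, s_hi = mf.support
            if s_lo < lo - 1e-9 or s_hi > hi + 1e-9:
                raise ConfigurationError(
                    f"variable {self.name!r}, label {label!r}: support "
                    f"[{s_lo}, {s_hi}] exceeds universe [{lo}, {hi}]"
                )
        # Completeness: some label must be active at every universe point,
        # otherwise singleton fuzzification could fire no rule at all.
        step = (hi - lo) / (self._COMPLETENESS_GRID - 1)
        for i in range(self._COMPLETENESS_GRID):
            x = min(lo + i * step, hi)  # guard the endpoint against round-up
            if all(mf(x) == 0.0 for mf in self.labels.values()):
                raise ConfigurationError(
                    f"variable {self.name!r}: no label covers x={x:g}"
                )

    def clamp(self, x: float) -> float:
        lo, hi = self.universe
        return min(max(x, lo), hi)

    def fuzzify(self, x: float) -> dict[str, float]:
        """Singleton fuzzification; out-of-universe inputs are clamped."""
        xc = self.clamp(x)
        return {label: mf(xc) for label, mf in self.labels.items()}

    def best_label(self, x: float) -> str:
        """Label of maximal membership at ``x``; ties go to the later label."""
        xc = self.clamp(x)
        best, best_deg = None, -1.0
        for label, mf in self.labels.items():
            deg = mf(xc)
            if deg >= best_deg:
                best, best_deg = label, deg
        assert best is not None
        return best

    def rename(self, name: str) -> "LinguisticVariable":
        return LinguisticVariable(name, self.universe, dict(self.labels))


def fuzzify_singleton(var: LinguisticVariable, x: float) -> dict[str, float]:
    """Singleton fuzzification of a crisp measurement, one degree per label."""
    return var.fuzzify(x)


def grade_letter(var: LinguisticVariable, crisp: float) -> str:
    """Map a crisp value back to its dominant label; ties break to the worse
    (later-declared) label."""
    return var.best_label(crisp)


@dataclass(frozen=True)
class FuzzyRule:
    """Conjunctive IF-THEN rule: every antecedent clause must hold (min)."""

    antecedent: Mapping[str, str]  # input variable name -> label
    consequent: str  # output label

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", dict(self.antecedent))


@dataclass(frozen=True)
class MamdaniSystem:
    """A complete Mamdani MISO system: inputs, one output, full rule base."""

    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    defuzz_method: str = "center_of_average"

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.defuzz_method not in DEFUZZ_METHODS:
            raise ConfigurationError(
                f"unknown defuzzification method {self.defuzz_method!r}"
            )
        names = [v.name for v in self.inputs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate input variable names: {names}")
        by_name = {v.name: v for v in self.inputs}
        seen: set[tuple[str, ...]] = set()
        for rule in self.rules:
            if set(rule.antecedent) != set(names):
                raise ConfigurationError(
                    f"rule {rule} must reference exactly the inputs {names}"
                )
            for var_name, label in rule.antecedent.items():
                if label not in by_name[var_name].labels:
                    raise ConfigurationError(
                        f"rule references unknown label {label!r} of "
                        f"variable {var_name!r}"
                    )
            if rule.consequent not in self.output.labels:
                raise ConfigurationError(
                    f"rule consequent {rule.consequent!r} is not a label of "
                    f"output {self.output.name!r}"
                )
            key = tuple(rule.antecedent[n] for n in names)
            if key in seen:
                raise ConfigurationError(f"duplicate rule for antecedent {key}")
            seen.add(key)
        # The rule base must tile the full cross-product of input labels so
        # that clamped inputs always fire at least one rule.
        expected = 1
        for v in self.inputs:
            expected *= len(v.labels)
        if len(self.rules) != expected:
            raise ConfigurationError(
                f"rule base must cover the input label cross-product exactly "
                f"once ({expected} rules), got {len(self.rules)}"
            )

    # -- inference ---------------------------------------------------------

    def fuzzify(self, crisp: Mapping[str, float]) -> dict[str, dict[str, float]]:
        missing = [v.name for v in self.inputs if v.name not in crisp]
        if missing:
            raise ContractViolationError(f"missing crisp inputs: {missing}")
        return {v.name: v.fuzzify(float(crisp[v.name])) for v in self.inputs}

    def evaluate_rules(
        self, fuzzified: Mapping[str, Mapping[str, float]]
    ) -> dict[str, float]:
        return evaluate_rules(self, fuzzified)

    def defuzzify(
        self, activations: Mapping[str, float], method: str | None = None
    ) -> float:
        return defuzzify(self.output, activations, method or self.defuzz_method)

    def evaluate(self, crisp: Mapping[str, float]) -> tuple[float, str]:
        """Crisp inputs -> (crisp output, dominant output label)."""
        activations = self.evaluate_rules(self.fuzzify(crisp))
        value = self.defuzzify(activations)
        return value, grade_letter(self.output, value)


def evaluate_rules(
    system: MamdaniSystem, fuzzified: Mapping[str, Mapping[str, float]]
) -> dict[str, float]:
    """Min-conjunction firing per rule, max aggregation per output label."""
    for var in system.inputs:
        if var.name not in fuzzified:
            raise ContractViolationError(
                f"fuzzified inputs lack variable {var.name!r}"
            )
    activations = {label: 0.0 for label in system.output.labels}
    for rule in system.rules:
        strength = min(
            fuzzified[var_name].get(label, 0.0)
            for var_name, label in rule.antecedent.items()
        )
        if strength > activations[rule.consequent]:
            activations[rule.consequent] = strength
    return activations


# -- defuzzification -------------------------------------------------------


def defuzzify(
    output: LinguisticVariable,
    activations: Mapping[str, float],
    method: str = "center_of_average",
) -> float:
    """Crisp value of an activation map over ``output``'s labels."""
    unknown = set(activations) - set(output.labels)
    if unknown:
        raise ContractViolationError(
            f"activations reference unknown labels {sorted(unknown)}"
        )
    if method == "center_of_average":
        return _center_of_average(output, activations)
    if method == "center_of_gravity":
        return _center_of_gravity(output, activations)
    raise ConfigurationError(f"unknown defuzzification method {method!r}")


def _center_of_average(
    output: LinguisticVariable, activations: Mapping[str, float]
) -> float:
    num = den = 0.0
    for label, act in activations.items():
        if act > 0.0:
            num += act * output.labels[label].peak
            den += act
    if den == 0.0:
        raise NoRuleFiredError(
            f"all activations zero on output {output.name!r}"
        )
    return num / den


def _clip_crossings(mf: MembershipFunction, level: float) -> list[float]:
    """Abscissae where ``min(level, mf(x))`` kinks, for 0 < level < 1."""
    bp = mf.breakpoints
    out = []
    if mf.shape == "triangular":
        a, b, c = bp
        lo = hi = b
    else:
        a, b, c, d = bp
        lo, hi, c = b, c, d
    if lo > a:
        out.append(a + level * (lo - a))
    if c > hi:
        out.append(c - level * (c - hi))
    return out


def _center_of_gravity(
    output: LinguisticVariable, activations: Mapping[str, float]
) -> float:
    """Exact centroid of max-aggregated, min-clipped piecewise-linear MFs."""
    acts = {l: float(activations.get(l, 0.0)) for l in output.labels}
    if all(a <= 0.0 for a in acts.values()):
        raise NoRuleFiredError(
            f"all activations zero on output {output.name!r}"
        )
    lo, hi = output.universe
    mfs = output.labels

    def g(x: float) -> float:
        return max(min(acts[l], mf(x)) for l, mf in mfs.items())

    kinks: set[float] = {lo, hi}
    for label, mf in mfs.items():
        kinks.update(b for b in mf.breakpoints if lo <= b <= hi)
        a = acts[label]
        if 0.0 < a < 1.0:
            kinks.update(x for x in _clip_crossings(mf, a) if lo <= x <= hi)
    base = sorted(kinks)

    # Within each base interval every clipped MF is affine; add pairwise
    # crossings so the upper envelope is affine on each refined interval.
    pts: set[float] = set(base)
    labels = list(mfs)
    for x0, x1 in zip(base, base[1:]):
        if x1 - x0 <= 1e-15:
            continue
        vals0 = [min(acts[l], mfs[l](x0)) for l in labels]
        vals1 = [min(acts[l], mfs[l](x1)) for l in labels]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                d0 = vals0[i] - vals0[j]
                d1 = vals1[i] - vals1[j]
                if d0 * d1 < 0.0:  # strict sign change inside the interval
                    t = d0 / (d0 - d1)
                    pts.add(x0 + t * (x1 - x0))
    grid = sorted(pts)

    num = den = 0.0
    for x0, x1 in zip(grid, grid[1:]):
        h = x1 - x0
        if h <= 0.0:
            continue
        xm = 0.5 * (x0 + x1)
        g0, gm, g1 = g(x0), g(xm), g(x1)
        den += h * 0.5 * (g0 + g1)
        # x * g(x) is quadratic on an affine segment: Simpson is exact.
        num += h / 6.0 * (x0 * g0 + 4.0 * xm * gm + x1 * g1)
    if den <= 0.0:
        raise NoRuleFiredError(
            f"aggregated output surface has zero area on {output.name!r}"
        )
    return num / den
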