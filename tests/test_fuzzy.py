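"""Mamdani core: membership shapes, fuzzification, rules, defuzzification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lapassess.exceptions import (
    ConfigurationError,
    ContractViolationError,
    NoRuleFiredError,
)
from lapassess.fuzzy import (
    FuzzyRule,
    LinguisticVariable,
    MamdaniSystem,
    MembershipFunction,
    defuzzify,
    evaluate_rules,
    fuzzify_singleton,
    grade_letter,
    membership_degree,
)

# -- independent grid oracle for centroid defuzzification ------------------


def _mf_on_grid(mf: MembershipFunction, x: np.ndarray) -> np.ndarray:
    """Vectorised piecewise-linear evaluation, written independently of
    MembershipFunction.__call__ (min-of-edges formula)."""
    bp = mf.breakpoints
    if mf.shape == "triangular":
        a, b, c, d = bp[0], bp[1], bp[1], bp[2]
    else:
        a, b, c, d = bp
    left = np.ones_like(x) if b == a else (x - a) / (b - a)
    right = np.ones_like(x) if d == c else (d - x) / (d - c)
    mu = np.clip(np.minimum(left, right), 0.0, 1.0)
    return np.where((x < a) | (x > d), 0.0, mu)


def grid_centroid(var: LinguisticVariable, activations: dict, n: int = 200_001):
    """Brute-force discrete centroid of the max-aggregated clipped surface."""
    x = np.linspace(*var.universe, n)
    agg = np.zeros_like(x)
    for label, mf in var.labels.items():
        agg = np.maximum(agg, np.minimum(activations.get(label, 0.0), _mf_on_grid(mf, x)))
    return float(np.trapezoid(agg * x, x) / np.trapezoid(agg, x))


def random_chain_variable(rng: np.random.Generator) -> LinguisticVariable:
    """A random complete variable: overlapping chain over random knots."""
    lo = float(rng.uniform(-50, 0))
    hi = lo + float(rng.uniform(10, 200))
    n_labels = int(rng.integers(3, 6))
    knots = np.sort(rng.uniform(lo, hi, n_labels - 2))
    knots = np.concatenate([[lo], knots, [hi]])
    labels = {}
    for i in range(n_labels):
        a = knots[max(i - 1, 0)]
        b = knots[i]
        c = knots[min(i + 1, n_labels - 1)]
        if rng.random() < 0.3 and a < b < c:
            mid = b + (c - b) * float(rng.uniform(0.05, 0.4))
            labels[f"L{i}"] = MembershipFunction("trapezoidal", (a, b, mid, c))
        else:
            labels[f"L{i}"] = MembershipFunction("triangular", (a, b, c))
    return LinguisticVariable("rand", (lo, hi), labels)


# -- membership functions --------------------------------------------------


@pytest.mark.parametrize(
    "shape,bp,x,expected",
    [
        ("triangular", (0, 5, 10), 5, 1.0),
        ("triangular", (0, 5, 10), 12, 0.0),
        ("triangular", (0, 5, 10), -1, 0.0),
        ("triangular", (0, 5, 10), 2.5, 0.5),
        ("triangular", (0, 5, 10), 7.5, 0.5),
        ("triangular", (0, 0, 12), 0, 1.0),  # left shoulder
        ("triangular", (0, 0, 12), 6, 0.5),
        ("triangular", (12, 24, 24), 24, 1.0),  # right shoulder
        ("trapezoidal", (0, 0, 10, 30), 0, 1.0),
        ("trapezoidal", (0, 0, 10, 30), 10, 1.0),
        ("trapezoidal", (0, 0, 10, 30), 20, 0.5),
        ("trapezoidal", (70, 90, 100, 100), 95, 1.0),
        ("trapezoidal", (70, 90, 100, 100), 80, 0.5),
    ],
)
def test_membership_degree_piecewise_linear(shape, bp, x, expected):
    mf = MembershipFunction(shape, bp)
    assert membership_degree(mf, x) == pytest.approx(expected)


@pytest.mark.parametrize(
    "shape,bp",
    [
        ("triangular", (5, 3, 10)),  # decreasing
        ("triangular", (0, 5)),  # wrong arity
        ("trapezoidal", (0, 5, 10)),  # wrong arity
        ("sigmoid", (0, 5, 10)),  # unknown shape
        ("triangular", (0, float("nan"), 10)),
    ],
)
def test_malformed_breakpoints_rejected(shape, bp):
    with pytest.raises(ConfigurationError):
        MembershipFunction(shape, bp)


def test_peak_is_plateau_midpoint_for_trapezoids():
    assert MembershipFunction("triangular", (0, 5, 10)).peak == 5
    assert MembershipFunction("trapezoidal", (0, 10, 20, 40)).peak == 15


@given(
    pts=st.lists(
        st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=3
    ),
    x=st.floats(-2e3, 2e3, allow_nan=False),
)
def test_membership_degree_always_in_unit_interval(pts, x):
    mf = MembershipFunction("triangular", tuple(sorted(pts)))
    assert 0.0 <= mf(x) <= 1.0


# -- linguistic variables and fuzzification --------------------------------


def test_variable_rejects_support_outside_universe():
    with pytest.raises(ConfigurationError):
        LinguisticVariable(
            "v", (0, 10), {"a": MembershipFunction("triangular", (0, 5, 12))}
        )


def test_variable_rejects_incomplete_coverage():
    # gap on (4, 6): no label has nonzero membership there
    with pytest.raises(ConfigurationError):
        LinguisticVariable(
            "v",
            (0, 10),
            {
                "a": MembershipFunction("triangular", (0, 0, 4)),
                "b": MembershipFunction("triangular", (6, 10, 10)),
            },
        )


def test_singleton_fuzzify_prototype_point(dist_var):
    degrees = fuzzify_singleton(dist_var, dist_var.labels["Close"].peak)
    assert degrees == {"Close": 1.0, "Middle": 0.0, "Far": 0.0}


def test_singleton_fuzzify_symmetric_crossover(dist_var):
    close = dist_var.labels["Close"]
    middle = dist_var.labels["Middle"]
    x = 0.5 * (close.peak + middle.peak)
    degrees = fuzzify_singleton(dist_var, x)
    assert degrees["Close"] == pytest.approx(0.5)
    assert degrees["Middle"] == pytest.approx(0.5)
    assert degrees["Far"] == pytest.approx(0.0)


def test_singleton_fuzzify_clamps_out_of_universe(dist_var):
    lo, hi = dist_var.universe
    assert fuzzify_singleton(dist_var, hi + 100) == fuzzify_singleton(dist_var, hi)
    assert fuzzify_singleton(dist_var, lo - 100) == fuzzify_singleton(dist_var, lo)


# -- rule evaluation -------------------------------------------------------


def _first_level(assessor):
    return assessor.first_level


def test_full_firing_single_rule(assessor):
    system = _first_level(assessor)
    fuzz = {
        "Dis_Cam1": {"Close": 1.0, "Middle": 0.0, "Far": 0.0},
        "H_Cam2": {"High": 0.0, "Field": 1.0, "Down": 0.0},
    }
    acts = evaluate_rules(system, fuzz)
    assert acts == {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0}


def test_all_zero_degrees_give_zero_activations(assessor):
    system = _first_level(assessor)
    fuzz = {
        "Dis_Cam1": {"Close": 0.0, "Middle": 0.0, "Far": 0.0},
        "H_Cam2": {"High": 0.0, "Field": 0.0, "Down": 0.0},
    }
    assert all(a == 0.0 for a in evaluate_rules(system, fuzz).values())


def test_partial_firing_min_conjunction_max_aggregation(assessor):
    # Hand-evaluated over the nine first-level rules: only the Field row
    # fires, Close->A at 0.6 and Middle->B at 0.4.
    system = _first_level(assessor)
    fuzz = {
        "Dis_Cam1": {"Close": 0.6, "Middle": 0.4, "Far": 0.0},
        "H_Cam2": {"High": 0.0, "Field": 1.0, "Down": 0.0},
    }
    acts = evaluate_rules(system, fuzz)
    assert acts == pytest.approx({"A": 0.6, "B": 0.4, "C": 0.0, "D": 0.0, "E": 0.0})


def test_missing_input_variable_is_contract_violation(assessor):
    with pytest.raises(ContractViolationError):
        evaluate_rules(_first_level(assessor), {"Dis_Cam1": {"Close": 1.0}})


def test_rule_base_must_cover_cross_product(dist_var, height_var, output_var):
    rules = tuple(
        FuzzyRule({"Dis_Cam1": d, "H_Cam2": h}, "C")
        for d in dist_var.labels
        for h in height_var.labels
    )
    MamdaniSystem((dist_var, height_var), output_var, rules)  # complete: fine
    with pytest.raises(ConfigurationError):
        MamdaniSystem((dist_var, height_var), output_var, rules[:-1])
    with pytest.raises(ConfigurationError):
        MamdaniSystem((dist_var, height_var), output_var, rules[:-1] + (rules[0],))


@given(st.data())
def test_raising_a_degree_never_lowers_activations(assessor, data):
    system = _first_level(assessor)
    base = {
        var.name: {
            label: data.draw(st.floats(0, 1), label=f"{var.name}.{label}")
            for label in var.labels
        }
        for var in system.inputs
    }
    acts = evaluate_rules(system, base)
    var = data.draw(st.sampled_from([v.name for v in system.inputs]))
    label = data.draw(st.sampled_from(sorted(base[var])))
    bumped = {v: dict(d) for v, d in base.items()}
    bumped[var][label] = min(1.0, bumped[var][label] + data.draw(st.floats(0, 1)))
    acts2 = evaluate_rules(system, bumped)
    assert all(acts2[l] >= acts[l] for l in acts)


# -- defuzzification -------------------------------------------------------


def test_center_of_average_single_symmetric_label():
    var = LinguisticVariable(
        "v",
        (0, 100),
        {
            "low": MembershipFunction("triangular", (0, 0, 50)),
            "mid": MembershipFunction("triangular", (0, 50, 100)),
            "high": MembershipFunction("triangular", (50, 100, 100)),
        },
    )
    assert defuzzify(var, {"mid": 1.0}, "center_of_average") == pytest.approx(50.0)
    assert defuzzify(var, {"mid": 1.0}, "center_of_gravity") == pytest.approx(50.0)


def test_center_of_average_balances_equal_activations():
    var = LinguisticVariable(
        "v",
        (0, 100),
        {
            "edge_lo": MembershipFunction("triangular", (0, 0, 25)),
            "lo": MembershipFunction("triangular", (0, 25, 75)),
            "hi": MembershipFunction("triangular", (25, 75, 100)),
            "edge_hi": MembershipFunction("triangular", (75, 100, 100)),
        },
    )
    assert defuzzify(var, {"lo": 0.4, "hi": 0.4}, "center_of_average") == pytest.approx(50.0)


def test_all_zero_activations_signal_no_rule_fired(output_var):
    with pytest.raises(NoRuleFiredError):
        defuzzify(output_var, {l: 0.0 for l in output_var.labels})
    with pytest.raises(NoRuleFiredError):
        defuzzify(output_var, {}, "center_of_gravity")


def test_unknown_activation_label_rejected(output_var):
    with pytest.raises(ContractViolationError):
        defuzzify(output_var, {"Z": 1.0})


def test_center_of_gravity_matches_fine_grid_oracle():
    rng = np.random.default_rng(1234)
    for _ in range(50):
        var = random_chain_variable(rng)
        acts = {l: float(rng.uniform(0, 1)) for l in var.labels}
        if max(acts.values()) < 0.2:
            acts[next(iter(acts))] = 0.5
        mine = defuzzify(var, acts, "center_of_gravity")
        ref = grid_centroid(var, acts)
        assert mine == pytest.approx(ref, rel=1e-6)


@pytest.mark.parametrize("method", ["center_of_average", "center_of_gravity"])
def test_defuzzified_value_stays_in_universe(output_var, method):
    rng = np.random.default_rng(7)
    lo, hi = output_var.universe
    for _ in range(200):
        acts = {l: float(rng.uniform(0, 1)) for l in output_var.labels}
        if max(acts.values()) == 0.0:
            continue
        assert lo <= defuzzify(output_var, acts, method) <= hi


@pytest.mark.parametrize("method", ["center_of_average", "center_of_gravity"])
def test_single_full_activation_grades_back_to_its_label(output_var, method):
    for label in output_var.labels:
        acts = {l: (1.0 if l == label else 0.0) for l in output_var.labels}
        crisp = defuzzify(output_var, acts, method)
        assert grade_letter(output_var, crisp) == label


# -- letter grading --------------------------------------------------------


def test_grade_letter_peaks_and_conservative_tie(output_var):
    assert grade_letter(output_var, output_var.labels["A"].peak) == "A"
    assert grade_letter(output_var, output_var.labels["E"].peak) == "E"
    # exact A/B crossover: equal membership, worse grade wins
    a, b = output_var.labels["A"], output_var.labels["B"]
    crossover = 0.5 * (a.breakpoints[0] + b.breakpoints[2])
    assert math.isclose(a(crossover), b(crossover))
    assert grade_letter(output_var, crossover) == "B"
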