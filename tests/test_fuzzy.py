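"""Unit and property tests for the Mamdani inference machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteofuzz.errors import (
    DefuzzificationError,
    DomainError,
    FuzzyConfigError,
    InputError,
)
from osteofuzz.fuzzy import (
    Clause,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    apply_rules,
    defuzzify_centroid,
    eval_membership,
    fuzzify,
    rules_from_text,
    rules_to_text,
)

tri = MembershipFunction.triangular
trap = MembershipFunction.trapezoidal
gauss = MembershipFunction.gaussian


class TestMembership:
    @pytest.mark.parametrize(
        "mf, x, expected",
        [
            (tri(0, 1, 2), 1.0, 1.0),  # apex
            (tri(0, 1, 2), 0.5, 0.5),
            (tri(0, 1, 2), -1.0, 0.0),
            (gauss(0.5, 0.05), 0.5, 1.0),  # center
            (trap(0, 1, 2, 3), 2.5, 0.5),  # descent midpoint
            (trap(0, 1, 2, 3), 1.5, 1.0),  # plateau
            (trap(0, 0, 1, 2), 0.0, 1.0),  # vertical left shoulder
        ],
    )
    def test_pointwise_values(self, mf, x, expected):
        assert eval_membership(mf, x) == pytest.approx(expected)

    def test_activation_caps_degree(self):
        mf = gauss(0.5, 0.05, activation=0.6)
        assert eval_membership(mf, 0.5) == pytest.approx(0.6)

    def test_non_finite_input_rejected(self):
        with pytest.raises(InputError):
            eval_membership(tri(0, 1, 2), float("nan"))

    @pytest.mark.parametrize(
        "bad",
        [
            lambda: tri(2, 1, 0),
            lambda: trap(0, 2, 1, 3),
            lambda: gauss(0.5, -0.1),
            lambda: MembershipFunction("gaussian", (0.5, 0.05), activation=1.5),
            lambda: MembershipFunction("sigmoid", (0.0, 1.0)),
        ],
    )
    def test_invalid_shapes_rejected(self, bad):
        with pytest.raises(FuzzyConfigError):
            bad()

    @given(st.floats(-10, 10))
    @settings(derandomize=True, max_examples=200)
    def test_degree_bounded(self, x):
        for mf in (tri(-1, 0, 2), trap(-3, -1, 1, 4), gauss(0.0, 0.5)):
            assert 0.0 <= eval_membership(mf, x) <= mf.activation


@pytest.fixture
def unity_partition():
    """Triangular fan forming a partition of unity on [0, 1]."""
    return LinguisticVariable(
        name="v",
        domain=(0.0, 1.0),
        levels={
            "lo": tri(0.0, 0.0, 0.5),
            "mid": tri(0.0, 0.5, 1.0),
            "hi": tri(0.5, 1.0, 1.0),
        },
    )


class TestFuzzify:
    def test_apex_and_crossing(self, unity_partition):
        at_apex = fuzzify(unity_partition, 0.0)
        assert at_apex == {"lo": 1.0, "mid": 0.0, "hi": 0.0}
        at_cross = fuzzify(unity_partition, 0.25)
        assert at_cross["lo"] == pytest.approx(0.5)
        assert at_cross["mid"] == pytest.approx(0.5)

    def test_partition_of_unity_sums_to_one(self, unity_partition):
        rng = np.random.default_rng(0)
        for x in rng.uniform(0, 1, size=1000):
            degrees = fuzzify(unity_partition, x)
            assert sum(degrees.values()) == pytest.approx(1.0)

    def test_out_of_domain_clamps_or_raises(self, unity_partition):
        assert fuzzify(unity_partition, 2.0)["hi"] == pytest.approx(1.0)
        with pytest.raises(DomainError):
            fuzzify(unity_partition, 2.0, clamp=False)

    def test_log_axis_maps_zero_to_lower_edge(self):
        var = LinguisticVariable(
            name="c",
            domain=(-2.0, 2.0),
            log10=True,
            levels={"neg": trap(-2, -2, -1, 0), "pos": trap(0, 1, 2, 2)},
        )
        assert fuzzify(var, 0.0)["neg"] == 1.0
        assert fuzzify(var, 10.0)["pos"] == 1.0


class TestRules:
    def test_min_and_semantics(self):
        rule = FuzzyRule(
            (Clause("a", "x"), Clause("b", "y")), consequent=("out", "L")
        )
        degrees = {"a": {"x": 0.7}, "b": {"y": 0.4}}
        assert rule.firing_strength(degrees) == pytest.approx(0.4)

    def test_max_aggregation_across_rules(self):
        rules = [
            FuzzyRule((Clause("a", "x"),), ("out", "L")),
            FuzzyRule((Clause("b", "y"),), ("out", "L")),
        ]
        agg = apply_rules(rules, {"a": {"x": 0.3}, "b": {"y": 0.8}})
        assert agg["out"]["L"] == pytest.approx(0.8)

    def test_not_clause_is_complement(self):
        rule = FuzzyRule((Clause("a", "x", negated=True),), ("out", "L"))
        assert rule.firing_strength({"a": {"x": 0.2}}) == pytest.approx(0.8)

    def test_unresolvable_reference_raises(self):
        rule = FuzzyRule((Clause("a", "missing"),), ("out", "L"))
        with pytest.raises(FuzzyConfigError):
            rule.firing_strength({"a": {"x": 0.2}})

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_aggregation(self, lo, hi):
        """Raising a rule's firing strength never lowers its level activation."""
        lo, hi = sorted((lo, hi))
        rules = [
            FuzzyRule((Clause("a", "x"),), ("out", "L")),
            FuzzyRule((Clause("b", "y"),), ("out", "L")),
        ]
        base = {"a": {"x": lo}, "b": {"y": 0.5}}
        bumped = {"a": {"x": hi}, "b": {"y": 0.5}}
        assert (
            apply_rules(rules, bumped)["out"]["L"]
            >= apply_rules(rules, base)["out"]["L"]
        )

    def test_text_round_trip(self):
        rules = [
            FuzzyRule(
                (Clause("TNF", "Stimulatory"), Clause("IL8", "Negligible", True)),
                ("ED", "Fast"),
            ),
            FuzzyRule((Clause("Mg", "Destructive"),), ("LD", "Slow")),
        ]
        assert rules_from_text(rules_to_text(rules)) == rules

    def test_malformed_rule_text_raises(self):
        with pytest.raises(FuzzyConfigError):
            rules_from_text("WHENEVER x THEN y")


def oracle_centroid(var, activations, n=100_000):
    """Independent brute-force centroid by trapezoid integration."""
    grid = np.linspace(var.domain[0], var.domain[1], n)
    mu = np.zeros_like(grid)
    for level, act in activations.items():
        mu = np.maximum(mu, np.minimum(eval_membership(var.levels[level], grid), act))
    return np.trapezoid(mu * grid, grid) / np.trapezoid(mu, grid)


@pytest.fixture
def gaussian_output():
    return LinguisticVariable(
        name="rate",
        domain=(0.0, 1.0),
        levels={
            "slow": gauss(0.3, 0.05),
            "physio": gauss(0.5, 0.05),
            "fast": gauss(0.7, 0.05),
        },
    )


class TestCentroid:
    def test_single_symmetric_level_returns_center(self, gaussian_output):
        for act in (0.1, 0.5, 1.0):
            crisp = defuzzify_centroid(gaussian_output, {"physio": act})
            assert crisp == pytest.approx(0.5, abs=1e-9)

    def test_symmetric_pair_returns_midpoint(self, gaussian_output):
        crisp = defuzzify_centroid(gaussian_output, {"slow": 0.6, "fast": 0.6})
        assert crisp == pytest.approx(0.5, abs=1e-9)

    def test_matches_brute_force_oracle(self, gaussian_output):
        rng = np.random.default_rng(42)
        for _ in range(100):
            acts = {
                level: float(a)
                for level, a in zip(
                    gaussian_output.levels, rng.uniform(0, 1, size=3)
                )
            }
            crisp = defuzzify_centroid(gaussian_output, acts)
            assert crisp == pytest.approx(
                oracle_centroid(gaussian_output, acts), abs=1e-3
            )
            assert 0.0 <= crisp <= 1.0

    def test_zero_activation_raises(self, gaussian_output):
        with pytest.raises(DefuzzificationError):
            defuzzify_centroid(gaussian_output, {"physio": 0.0})

    def test_unknown_level_raises(self, gaussian_output):
        with pytest.raises(FuzzyConfigError):
            defuzzify_centroid(gaussian_output, {"bogus": 1.0})
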