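"""Generic Mamdani fuzzy-inference machinery.

Implements the classical min/max semantics: rule firing strength is the
minimum over antecedent clause degrees (a negated clause contributes the
standard complement ``1 - mu``), implication clips the consequent membership
at the firing strength, per-level activations are aggregated with max across
rules, and the crisp output is the centroid of the max-union of the clipped
output memberships on a uniform grid.

Membership shapes are the three used throughout this model family:
piecewise-linear triangles and trapezoids for the inputs, Gaussians for the
output levels.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DefuzzificationError,
    DomainError,
    FuzzyConfigError,
    InputError,
)

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "Clause",
    "FuzzyRule",
    "eval_membership",
    "fuzzify",
    "apply_rules",
    "defuzzify_centroid",
    "rules_to_text",
    "rules_from_text",
]

#: grid resolution used for centroid defuzzification; 1001 points over a
#: unit interval resolve a sigma=0.05 Gaussian with ~50 points per s.d.
DEFAULT_GRID_POINTS = 1001


@dataclass(frozen=True)
class MembershipFunction:
    """A parametric membership shape returning degrees in [0, activation].

    ``kind`` is one of ``triangular`` (params a <= b <= c), ``trapezoidal``
    (params a <= b <= c <= d) or ``gaussian`` (params center, sigma).
    ``activation`` caps the degree; 1.0 for all shapes used here.
    """

    kind: str
    params: tuple[float, ...]
    activation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.activation <= 1.0:
            raise FuzzyConfigError(
                f"activation must be in (0, 1], got {self.activation}"
            )
        if self.kind == "triangular":
            if len(self.params) != 3:
                raise FuzzyConfigError("triangular needs (a, b, c)")
            a, b, c = self.params
            if not a <= b <= c:
                raise FuzzyConfigError(
                    f"triangular abscissae must be non-decreasing: {self.params}"
                )
        elif self.kind == "trapezoidal":
            if len(self.params) != 4:
                raise FuzzyConfigError("trapezoidal needs (a, b, c, d)")
            a, b, c, d = self.params
            if not a <= b <= c <= d:
                raise FuzzyConfigError(
                    f"trapezoidal abscissae must be non-decreasing: {self.params}"
                )
        elif self.kind == "gaussian":
            if len(self.params) != 2:
                raise FuzzyConfigError("gaussian needs (center, sigma)")
            if self.params[1] <= 0:
                raise FuzzyConfigError(f"gaussian sigma must be > 0: {self.params}")
        else:
            raise FuzzyConfigError(f"unknown membership kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def triangular(cls, a: float, b: float, c: float) -> "MembershipFunction":
        return cls("triangular", (float(a), float(b), float(c)))

    @classmethod
    def trapezoidal(
        cls, a: float, b: float, c: float, d: float
    ) -> "MembershipFunction":
        return cls("trapezoidal", (float(a), float(b), float(c), float(d)))

    @classmethod
    def gaussian(
        cls, center: float, sigma: float, activation: float = 1.0
    ) -> "MembershipFunction":
        return cls("gaussian", (float(center), float(sigma)), float(activation))

    # -- evaluation --------------------------------------------------------
    def __call__(self, x):
        return eval_membership(self, x)


def _ramp_up(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Linear 0->1 ramp on [a, b]; an inclusive vertical edge when a == b."""
    if a == b:
        return (x >= a).astype(float)
    return np.clip((x - a) / (b - a), 0.0, 1.0)


def _ramp_down(x: np.ndarray, c: float, d: float) -> np.ndarray:
    """Linear 1->0 ramp on [c, d]; an inclusive vertical edge when c == d."""
    if c == d:
        return (x <= d).astype(float)
    return np.clip((d - x) / (d - c), 0.0, 1.0)


def eval_membership(mf: MembershipFunction, x):
    """Degree of membership of ``x`` (scalar or array) in ``mf``."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("membership input must be finite")
    if mf.kind == "triangular":
        a, b, c = mf.params
        mu = np.minimum(_ramp_up(arr, a, b), _ramp_down(arr, b, c))
        mu = np.where((arr < a) | (arr > c), 0.0, mu)
    elif mf.kind == "trapezoidal":
        a, b, c, d = mf.params
        mu = np.minimum(_ramp_up(arr, a, b), _ramp_down(arr, c, d))
        mu = np.where((arr < a) | (arr > d), 0.0, mu)
    else:  # gaussian
        center, sigma = mf.params
        mu = np.exp(-((arr - center) ** 2) / (2.0 * sigma**2))
    mu = mu * mf.activation
    if np.ndim(x) == 0:
        return float(mu)
    return mu


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable with a crisp domain and a set of linguistic levels.

    ``log10`` marks variables fuzzified on a decadic-log axis (cytokine
    concentrations span four decades); the domain and all membership
    abscissae are then in log10 units and crisp values are transformed
    before evaluation, with zero/negative concentrations mapped to the
    lower domain edge.
    """

    name: str
    domain: tuple[float, float]
    levels: dict[str, MembershipFunction]
    units: str = ""
    log10: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise FuzzyConfigError(f"empty domain for {self.name!r}: {self.domain}")
        if len(self.levels) == 0:
            raise FuzzyConfigError(f"variable {self.name!r} has no levels")

    def to_internal(self, x: float) -> float:
        """Map a crisp value onto the variable's internal (possibly log) axis."""
        if not math.isfinite(x):
            raise InputError(f"{self.name}: non-finite input {x}")
        if self.log10:
            if x <= 0.0:
                return self.domain[0]
            return math.log10(x)
        return x


def fuzzify(
    var: LinguisticVariable, x: float, clamp: bool = True
) -> dict[str, float]:
    """Map a crisp value to a degree per level of ``var``.

    Values outside the domain are clamped to the boundary by default, so
    concentrations above the last anchor behave as the extreme level; with
    ``clamp=False`` they raise :class:`DomainError` instead.
    """
    z = var.to_internal(float(x))
    lo, hi = var.domain
    if z < lo or z > hi:
        if not clamp:
            raise DomainError(
                f"{var.name}: value {x} outside domain {var.domain}"
            )
        z = min(max(z, lo), hi)
    return {name: eval_membership(mf, z) for name, mf in var.levels.items()}


@dataclass(frozen=True)
class Clause:
    """One antecedent condition: ``variable IS [NOT] level``."""

    variable: str
    level: str
    negated: bool = False


@dataclass(frozen=True)
class FuzzyRule:
    """AND-conjunction of clauses implying one output level."""

    antecedent: tuple[Clause, ...]
    consequent: tuple[str, str]  # (output variable, output level)

    def __post_init__(self) -> None:
        if len(self.antecedent) == 0:
            raise FuzzyConfigError("rule antecedent must be non-empty")

    def firing_strength(self, degrees: dict[str, dict[str, float]]) -> float:
        strength = 1.0
        for clause in self.antecedent:
            try:
                mu = degrees[clause.variable][clause.level]
            except KeyError as exc:
                raise FuzzyConfigError(
                    f"rule references unknown {clause.variable!r}/{clause.level!r}"
                ) from exc
            if clause.negated:
                mu = 1.0 - mu
            strength = min(strength, mu)
        return strength


def apply_rules(
    rules: list[FuzzyRule] | tuple[FuzzyRule, ...],
    degrees: dict[str, dict[str, float]],
) -> dict[str, dict[str, float]]:
    """Evaluate all rules and max-aggregate activations per output level.

    Returns a mapping output-variable -> level -> activation in [0, 1].
    Levels never named as a consequent do not appear in the result.
    """
    out: dict[str, dict[str, float]] = {}
    for rule in rules:
        strength = rule.firing_strength(degrees)
        var, level = rule.consequent
        per_var = out.setdefault(var, {})
        per_var[level] = max(per_var.get(level, 0.0), strength)
    return out


def defuzzify_centroid(
    var: LinguisticVariable,
    activations: dict[str, float],
    n_points: int = DEFAULT_GRID_POINTS,
) -> float:
    """Centroid of the max-union of min-clipped level memberships.

    Each activated level's membership is clipped at its activation, the
    clipped curves are combined with pointwise max, and the crisp output is
    the area centroid on a uniform ``n_points`` grid over the domain.
    """
    for level in activations:
        if level not in var.levels:
            raise FuzzyConfigError(
                f"activation references unknown level {level!r} of {var.name!r}"
            )
    grid = np.linspace(var.domain[0], var.domain[1], n_points)
    mu = np.zeros_like(grid)
    for level, act in activations.items():
        if act <= 0.0:
            continue
        mu = np.maximum(mu, np.minimum(eval_membership(var.levels[level], grid), act))
    total = float(np.sum(mu))
    if total <= 0.0:
        raise DefuzzificationError(
            f"all activations zero for {var.name!r}; rule base does not cover "
            "the presented state"
        )
    return float(np.sum(mu * grid) / total)


# -- plain-text rule (de)serialization ------------------------------------
# Rules round-trip through the IF/THEN phrasing used in supplementary rule
# listings, e.g. "IF TNF IS Stimulatory AND IL8 IS NOT Negligible THEN ED IS Fast".

_RULE_RE = re.compile(r"^IF\s+(.+?)\s+THEN\s+(\S+)\s+IS\s+(\S+)\s*$", re.IGNORECASE)
_CLAUSE_RE = re.compile(r"^(\S+)\s+IS\s+(NOT\s+)?(\S+)$", re.IGNORECASE)


def rules_to_text(rules: list[FuzzyRule] | tuple[FuzzyRule, ...]) -> str:
    lines = []
    for rule in rules:
        parts = [
            f"{c.variable} IS {'NOT ' if c.negated else ''}{c.level}"
            for c in rule.antecedent
        ]
        var, level = rule.consequent
        lines.append(f"IF {' AND '.join(parts)} THEN {var} IS {level}")
    return "\n".join(lines) + "\n"


def rules_from_text(text: str) -> list[FuzzyRule]:
    rules = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _RULE_RE.match(line)
        if m is None:
            raise FuzzyConfigError(f"line {lineno}: cannot parse rule {line!r}")
        clauses = []
        for part in re.split(r"\s+AND\s+", m.group(1), flags=re.IGNORECASE):
            cm = _CLAUSE_RE.match(part.strip())
            if cm is None:
                raise FuzzyConfigError(f"line {lineno}: bad clause {part!r}")
            clauses.append(
                Clause(cm.group(1), cm.group(3), negated=cm.group(2) is not None)
            )
        rules.append(FuzzyRule(tuple(clauses), (m.group(2), m.group(3))))
    return rules
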