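"""The osteogenic-differentiation fuzzy controller.

Five extracellular signals — Mg2+ ions and the cytokines TNF-alpha, IL-10,
IL-8 and IL-1beta — are fuzzified into linguistic levels, a Mamdani rule
base encodes their known stimulatory/inhibitory roles, and centroid
defuzzification yields two crisp rates in [0, 1]: the fuzzy early (ED) and
late (LD) differentiation rates, with 0.5 denoting the physiological rate.

Membership anchors follow the textual evidence the rule base was built
from:

* Mg2+: 0.8 mM physiological (standard MEM), sub-physiological
  concentrations delay early differentiation, 2-10 mM stimulate it (peak at
  the free parameter ``p_ms``), > 1.8 mM inhibits late differentiation, and
  > 20 mM compromises viability.
* TNF-alpha: stimulatory at 1 ng/ml, neutral at 10 ng/ml, inhibitory at
  100 ng/ml.
* IL-10: exposure-dependent. Applied for at most 48 h the stimulation grows
  monotonically from 0 to 10 ng/ml; applied longer it peaks at 0.1 ng/ml
  and becomes inhibitory at >= 10 ng/ml.
* IL-8: stimulation rises rapidly from 0 to 100 ng/ml through an
  intermediate Favorable state peaking at ``p_8f``.
* IL-1beta: stimulatory in a low window (peak ``p_1bs``, effect ending at
  ``p_1bie``), and an antagonist of IL-8: both present together cap the
  response below the IL-8-alone maximum.

Cytokine axes are fuzzified on a log10 scale (anchors span four decades);
the Mg axis is linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .errors import FuzzyConfigError, InputError
from .fuzzy import (
    Clause,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    apply_rules,
    defuzzify_centroid,
    fuzzify,
)

__all__ = [
    "CellInputs",
    "ControllerParams",
    "RateOutputs",
    "IL10_SWITCH_HOURS",
    "build_mg_variable",
    "build_tnf_variable",
    "build_il10_variable",
    "build_il8_variable",
    "build_il1b_variable",
    "build_ed_output",
    "build_ld_output",
    "build_rule_base",
    "infer_rates",
    "clear_rate_cache",
]

#: IL-10 application time separating short- from long-term treatment [hours]
IL10_SWITCH_HOURS = 48.0

#: log10 axis shared by all cytokine variables: 1e-4 ... 1e3 ng/ml
_LOG_DOMAIN = (-4.0, 3.0)

#: sigma of the Gaussian output levels
OUTPUT_SIGMA = 0.05

#: center of the Extremely-fast ED level (fixed, not a free parameter)
EXTREMELY_FAST_CENTER = 0.95

#: center of the Very-fast LD level (fixed, not a free parameter)
LD_VERY_FAST_CENTER = 0.9

_tri = MembershipFunction.triangular
_trap = MembershipFunction.trapezoidal
_gauss = MembershipFunction.gaussian


@dataclass(frozen=True)
class CellInputs:
    """The five signal concentrations plus cumulative IL-10 exposure.

    Concentrations: ``mg`` in mM, cytokines in ng/ml; ``il10_exposure`` in
    hours selects between the short- and long-term IL-10 fuzzifiers.
    """

    mg: float = 0.8
    tnf: float = 0.0
    il10: float = 0.0
    il8: float = 0.0
    il1b: float = 0.0
    il10_exposure: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mg", "tnf", "il10", "il8", "il1b", "il10_exposure"):
            v = getattr(self, name)
            if v < 0:
                raise InputError(f"{name} must be >= 0, got {v}")

    @classmethod
    def physiological(cls) -> "CellInputs":
        return cls()


@dataclass(frozen=True)
class ControllerParams:
    """Free membership parameters of the controller.

    Concentration anchors: ``p_ms`` (Mg stimulatory peak, mM), ``p_md``
    (onset of the Mg ineffective-to-inhibitory transition, mM), ``p_8f``
    (IL-8 Favorable peak, ng/ml), ``p_1bs``/``p_1bie`` (peak and end of the
    IL-1beta stimulatory window, ng/ml). Output-level centers
    (dimensionless rates): ``p_es``/``p_ef``/``p_evf`` for ED Slow, Fast and
    Very fast; ``p_ls``/``p_lf`` for LD Slow and Fast.
    """

    p_ms: float = 7.0
    p_md: float = 15.0
    p_8f: float = 10.0
    p_1bs: float = 10.0
    p_1bie: float = 50.0
    p_es: float = 0.3
    p_ef: float = 0.7
    p_evf: float = 0.9
    p_ls: float = 0.3
    p_lf: float = 0.7

    def __post_init__(self) -> None:
        if not 2.0 <= self.p_ms <= 10.0:
            raise FuzzyConfigError(f"p_ms must lie in [2, 10] mM, got {self.p_ms}")
        if not self.p_md > self.p_ms:
            raise FuzzyConfigError("p_md must exceed p_ms")
        if not 0.0 < self.p_es < 0.5 < self.p_ef < self.p_evf < 1.0:
            raise FuzzyConfigError("need 0 < p_es < 0.5 < p_ef < p_evf < 1")
        if not 0.0 < self.p_ls < 0.5 < self.p_lf < 1.0:
            raise FuzzyConfigError("need 0 < p_ls < 0.5 < p_lf < 1")
        if not self.p_1bs < self.p_1bie:
            raise FuzzyConfigError("p_1bs must be below p_1bie")
        if not self.p_8f > 0 or not self.p_1bs > 0:
            raise FuzzyConfigError("concentration anchors must be positive")


@dataclass(frozen=True)
class RateOutputs:
    """Crisp fuzzy rates; 0.5 is the physiological rate."""

    f_e: float
    f_l: float


# ---------------------------------------------------------------------------
# input variables
# ---------------------------------------------------------------------------

def build_mg_variable(params: ControllerParams) -> LinguisticVariable:
    """Six Mg2+ levels on a linear mM axis, domain [0, 30]."""
    p_ms, p_md = params.p_ms, params.p_md
    return LinguisticVariable(
        name="Mg",
        domain=(0.0, 30.0),
        units="mM",
        levels={
            "InhibitoryED": _trap(0.0, 0.0, 0.4, 0.8),
            "Physiological": _tri(0.4, 0.8, 1.8),
            "Stimulatory": _tri(0.8, p_ms, p_md),
            "Ineffective": _tri(p_ms, p_md, 20.0),
            "InhibitoryLD": _trap(1.8, 10.0, 30.0, 30.0),
            "Destructive": _trap(min(p_md, 20.0), 20.0, 30.0, 30.0),
        },
    )


def build_tnf_variable() -> LinguisticVariable:
    """TNF-alpha: stimulatory at 1, neutral at 10, inhibitory at 100 ng/ml."""
    return LinguisticVariable(
        name="TNF",
        domain=_LOG_DOMAIN,
        units="ng/ml",
        log10=True,
        levels={
            "Negligible": _trap(-4.0, -4.0, -2.0, 0.0),
            "Stimulatory": _tri(-2.0, 0.0, 1.0),
            "Ineffective": _tri(0.0, 1.0, 2.0),
            "Inhibitory": _trap(1.0, 2.0, 3.0, 3.0),
        },
    )


def build_il10_variable(exposure_h: float) -> LinguisticVariable:
    """IL-10 fuzzifier selected by cumulative application time.

    Short-term (exposure <= 48 h): stimulation increases monotonically from
    0 to 10 ng/ml. Long-term: stimulation peaks at 0.1 ng/ml and the
    Inhibitory level dominates at >= 10 ng/ml.
    """
    if exposure_h < 0:
        raise InputError(f"exposure must be >= 0, got {exposure_h}")
    if exposure_h <= IL10_SWITCH_HOURS:
        levels = {
            "Negligible": _trap(-4.0, -4.0, -3.0, -1.0),
            "Favorable": _tri(-3.0, -1.0, 1.0),
            "Stimulatory": _trap(-1.0, 1.0, 2.0, 3.0),
            "Inhibitory": _trap(2.0, 3.0, 3.0, 3.0),
        }
    else:
        levels = {
            "Negligible": _trap(-4.0, -4.0, -3.0, -2.0),
            "Favorable": _tri(-3.0, -2.0, -1.0),
            "Stimulatory": _tri(-2.0, -1.0, 1.0),
            "Inhibitory": _trap(-1.0, 1.0, 3.0, 3.0),
        }
    return LinguisticVariable(
        name="IL10", domain=_LOG_DOMAIN, units="ng/ml", log10=True, levels=levels
    )


def build_il8_variable(params: ControllerParams) -> LinguisticVariable:
    """IL-8: Negligible / Favorable (peak p_8f) / Stimulatory (to 100 ng/ml)."""
    z8f = math.log10(params.p_8f)
    if not -3.0 < z8f < 2.0:
        raise FuzzyConfigError("p_8f must lie strictly between 1e-3 and 100 ng/ml")
    return LinguisticVariable(
        name="IL8",
        domain=_LOG_DOMAIN,
        units="ng/ml",
        log10=True,
        levels={
            "Negligible": _trap(-4.0, -4.0, -3.0, z8f),
            "Favorable": _tri(-3.0, z8f, 2.0),
            "Stimulatory": _trap(z8f, 2.0, 3.0, 3.0),
        },
    )


def build_il1b_variable(params: ControllerParams) -> LinguisticVariable:
    """IL-1beta: stimulatory window peaking at p_1bs, ending at p_1bie."""
    z1 = math.log10(params.p_1bs)
    z2 = math.log10(params.p_1bie)
    if not -1.0 < z1 < z2 <= 3.0:
        raise FuzzyConfigError(
            "need 0.1 ng/ml < p_1bs < p_1bie <= 1000 ng/ml"
        )
    return LinguisticVariable(
        name="IL1b",
        domain=_LOG_DOMAIN,
        units="ng/ml",
        log10=True,
        levels={
            "Negligible": _trap(-4.0, -4.0, -3.0, -1.0),
            "Stimulatory": _tri(-1.0, z1, z2),
            "Ineffective": _trap(z1, z2, 3.0, 3.0),
        },
    )


# ---------------------------------------------------------------------------
# output variables
# ---------------------------------------------------------------------------

def build_ed_output(params: ControllerParams) -> LinguisticVariable:
    """Six Gaussian ED rate levels on [0, 1], sigma 0.05, activation 1.

    ``Arrested`` (center 0.05) is never named by a rule; it completes the
    stated six-level inventory without influencing inference.
    """
    return LinguisticVariable(
        name="ED",
        domain=(0.0, 1.0),
        levels={
            "Arrested": _gauss(0.05, OUTPUT_SIGMA),
            "Slow": _gauss(params.p_es, OUTPUT_SIGMA),
            "Physiological": _gauss(0.5, OUTPUT_SIGMA),
            "Fast": _gauss(params.p_ef, OUTPUT_SIGMA),
            "VeryFast": _gauss(params.p_evf, OUTPUT_SIGMA),
            "ExtremelyFast": _gauss(EXTREMELY_FAST_CENTER, OUTPUT_SIGMA),
        },
    )


def build_ld_output(params: ControllerParams) -> LinguisticVariable:
    """Five Gaussian LD rate levels on [0, 1] (``Arrested`` again unused)."""
    return LinguisticVariable(
        name="LD",
        domain=(0.0, 1.0),
        levels={
            "Arrested": _gauss(0.05, OUTPUT_SIGMA),
            "Slow": _gauss(params.p_ls, OUTPUT_SIGMA),
            "Physiological": _gauss(0.5, OUTPUT_SIGMA),
            "Fast": _gauss(params.p_lf, OUTPUT_SIGMA),
            "VeryFast": _gauss(LD_VERY_FAST_CENTER, OUTPUT_SIGMA),
        },
    )


# ---------------------------------------------------------------------------
# rule base
# ---------------------------------------------------------------------------

def _rule(consequent: tuple[str, str], *clauses: Clause) -> FuzzyRule:
    return FuzzyRule(tuple(clauses), consequent)


def build_rule_base() -> list[FuzzyRule]:
    """The osteogenic rule base.

    "Any of" rows become one rule per listed input (OR realized through max
    aggregation); "simultaneously" rows become AND conjunctions, with
    or-groups inside a conjunction expanded into one rule per combination.
    "Not <level>" uses the standard complement.
    """
    C = Clause
    rules: list[FuzzyRule] = []

    # --- early differentiation -------------------------------------------
    for clause in (
        C("TNF", "Inhibitory"),
        C("IL10", "Inhibitory"),
        C("Mg", "InhibitoryED"),
        C("Mg", "Destructive"),
    ):
        rules.append(_rule(("ED", "Slow"), clause))
    for tnf_level in ("Negligible", "Ineffective"):
        for il1b_level in ("Negligible", "Ineffective"):
            for mg_level in ("Physiological", "Ineffective"):
                rules.append(
                    _rule(
                        ("ED", "Physiological"),
                        C("TNF", tnf_level),
                        C("IL10", "Negligible"),
                        C("IL8", "Negligible"),
                        C("IL1b", il1b_level),
                        C("Mg", mg_level),
                    )
                )
    for clause in (
        C("TNF", "Stimulatory"),
        C("IL10", "Favorable"),
        C("Mg", "Stimulatory"),
    ):
        rules.append(_rule(("ED", "Fast"), clause))
    rules.append(_rule(("ED", "VeryFast"), C("IL10", "Stimulatory")))
    rules.append(
        _rule(("ED", "VeryFast"), C("IL8", "Favorable"), C("IL1b", "Negligible"))
    )
    rules.append(
        _rule(("ED", "VeryFast"), C("IL8", "Negligible"), C("IL1b", "Stimulatory"))
    )
    # IL-1beta antagonism: both cytokines present cap the response at VeryFast
    rules.append(
        _rule(
            ("ED", "VeryFast"),
            C("IL8", "Negligible", negated=True),
            C("IL1b", "Negligible", negated=True),
        )
    )
    rules.append(
        _rule(
            ("ED", "ExtremelyFast"),
            C("IL8", "Stimulatory"),
            C("IL1b", "Negligible"),
        )
    )

    # --- late differentiation --------------------------------------------
    for clause in (
        C("TNF", "Inhibitory"),
        C("IL10", "Inhibitory"),
        C("Mg", "InhibitoryLD"),
        C("Mg", "Destructive"),
    ):
        rules.append(_rule(("LD", "Slow"), clause))
    for tnf_level in ("Negligible", "Ineffective"):
        rules.append(
            _rule(
                ("LD", "Physiological"),
                C("TNF", tnf_level),
                C("IL10", "Negligible"),
                C("Mg", "InhibitoryLD", negated=True),
            )
        )
    for clause in (C("TNF", "Stimulatory"), C("IL10", "Favorable")):
        rules.append(_rule(("LD", "Fast"), clause))
    rules.append(_rule(("LD", "VeryFast"), C("IL10", "Stimulatory")))
    return rules


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

_RULES = tuple(build_rule_base())


@lru_cache(maxsize=262144)
def _infer_cached(cp_key: tuple, inputs_key: tuple) -> tuple[float, float]:
    params = ControllerParams(*cp_key)
    mg, tnf, il10, il8, il1b, exposure = inputs_key
    degrees = {
        "Mg": fuzzify(build_mg_variable(params), mg),
        "TNF": fuzzify(build_tnf_variable(), tnf),
        "IL10": fuzzify(build_il10_variable(exposure), il10),
        "IL8": fuzzify(build_il8_variable(params), il8),
        "IL1b": fuzzify(build_il1b_variable(params), il1b),
    }
    agg = apply_rules(_RULES, degrees)
    f_e = defuzzify_centroid(build_ed_output(params), agg.get("ED", {}))
    f_l = defuzzify_centroid(build_ld_output(params), agg.get("LD", {}))
    return f_e, f_l


def infer_rates(inputs: CellInputs, params: ControllerParams) -> RateOutputs:
    """Crisp early/late differentiation rates for one input state.

    Results are memoized on the (parameters, inputs) pair: during
    calibration the same controller state is evaluated thousands of times.
    """
    cp_key = (
        params.p_ms, params.p_md, params.p_8f, params.p_1bs, params.p_1bie,
        params.p_es, params.p_ef, params.p_evf, params.p_ls, params.p_lf,
    )
    inputs_key = (
        inputs.mg, inputs.tnf, inputs.il10, inputs.il8, inputs.il1b,
        inputs.il10_exposure,
    )
    f_e, f_l = _infer_cached(cp_key, inputs_key)
    return RateOutputs(f_e=f_e, f_l=f_l)


def clear_rate_cache() -> None:
    _infer_cached.cache_clear()
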