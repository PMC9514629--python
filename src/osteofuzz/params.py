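"""The 30-entry free-parameter registry and prior specification.

The combined-calibration registry holds exactly 30 parameters:

* 5 input-membership anchors: p_ms, p_md, p_8f, p_1bs, p_1bie
* 5 output-level centers: p_es, p_ef, p_evf, p_ls, p_lf
* maturation threshold M_t and full differentiation time T_d
* 4 rate-scaling coefficients: alpha_es, alpha_ei, alpha_ls, alpha_li
* 3 marker baselines (beta) and 3 nonlinearity exponents (n) for ALP/OC/ARS
* 8 per-study correction factors k_{marker,study}

Per-study calibration exposes only the subset relevant to that study's
signals and markers (other studies' correction factors are always
excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .controller import ControllerParams
from .errors import ParameterError

__all__ = [
    "ParameterPrior",
    "ModelParameters",
    "REGISTRY",
    "default_priors",
    "relevant_parameters",
]


@dataclass(frozen=True)
class ParameterPrior:
    """Uniform prior bounds; ``scale`` marks parameters searched in log10."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"  # linear | log

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ParameterError(f"{self.name}: lower must be < upper")
        if self.scale not in ("linear", "log"):
            raise ParameterError(f"{self.name}: unknown scale {self.scale!r}")

    @property
    def length(self) -> float:
        """Prior length on the search axis (log10 units for log scale)."""
        import math

        if self.scale == "log":
            return math.log10(self.upper) - math.log10(self.lower)
        return self.upper - self.lower


@dataclass(frozen=True)
class ModelParameters:
    # membership anchors [mM / ng/ml]
    p_ms: float = 7.0
    p_md: float = 15.0
    p_8f: float = 10.0
    p_1bs: float = 10.0
    p_1bie: float = 50.0
    # output-level centers [dimensionless rate]
    p_es: float = 0.3
    p_ef: float = 0.7
    p_evf: float = 0.9
    p_ls: float = 0.3
    p_lf: float = 0.7
    # dynamics
    m_t: float = 0.4
    t_d: float = 21.0  # days
    alpha_es: float = 0.5
    alpha_ei: float = 0.5
    alpha_ls: float = 0.5
    alpha_li: float = 0.5
    # marker mapping
    beta_alp: float = 0.5
    beta_oc: float = 0.5
    beta_ars: float = 0.5
    n_alp: float = 1.0
    n_oc: float = 1.0
    n_ars: float = 1.0
    # per-study correction factors [marker units]
    k_alp_1: float = 1.0
    k_alp_2: float = 1.0
    k_oc_2: float = 1.0
    k_alp_3: float = 1.0
    k_ars_3: float = 1.0
    k_alp_4: float = 1.0
    k_ars_4: float = 1.0
    k_alp_5: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.m_t < 1.0:
            raise ParameterError(f"m_t must lie in (0, 1), got {self.m_t}")
        if self.t_d <= 0.0:
            raise ParameterError(f"t_d must be > 0, got {self.t_d}")
        for name in ("alpha_es", "alpha_ei", "alpha_ls", "alpha_li"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("beta_alp", "beta_oc", "beta_ars"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("n_alp", "n_oc", "n_ars"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be > 0")
        for f in fields(self):
            if f.name.startswith("k_") and getattr(self, f.name) <= 0.0:
                raise ParameterError(f"{f.name} must be > 0")

    # -- views -------------------------------------------------------------
    def controller(self) -> ControllerParams:
        return ControllerParams(
            p_ms=self.p_ms, p_md=self.p_md, p_8f=self.p_8f,
            p_1bs=self.p_1bs, p_1bie=self.p_1bie,
            p_es=self.p_es, p_ef=self.p_ef, p_evf=self.p_evf,
            p_ls=self.p_ls, p_lf=self.p_lf,
        )

    def correction_factor(self, marker: str, study: int) -> float:
        key = f"k_{marker.lower()}_{study}"
        if not hasattr(self, key):
            raise ParameterError(
                f"no correction factor for marker {marker!r} in study {study}"
            )
        return getattr(self, key)

    def beta(self, marker: str) -> float:
        return getattr(self, f"beta_{marker.lower()}")

    def n(self, marker: str) -> float:
        return getattr(self, f"n_{marker.lower()}")

    def replace(self, **updates: float) -> "ModelParameters":
        return replace(self, **updates)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: the definitive registry order used for combined calibration (30 entries)
REGISTRY: tuple[str, ...] = tuple(f.name for f in fields(ModelParameters))


def default_priors() -> dict[str, ParameterPrior]:
    """Default uniform priors; correction factors are searched in log10."""
    priors = {
        "p_ms": ParameterPrior("p_ms", 2.0, 10.0),
        "p_md": ParameterPrior("p_md", 10.0, 20.0),
        "p_8f": ParameterPrior("p_8f", 1.0, 100.0, scale="log"),
        "p_1bs": ParameterPrior("p_1bs", 1.0, 10.0),
        "p_1bie": ParameterPrior("p_1bie", 10.0, 100.0),
        "p_es": ParameterPrior("p_es", 0.05, 0.45),
        "p_ef": ParameterPrior("p_ef", 0.55, 0.95),
        "p_evf": ParameterPrior("p_evf", 0.6, 0.99),
        "p_ls": ParameterPrior("p_ls", 0.05, 0.45),
        "p_lf": ParameterPrior("p_lf", 0.55, 0.95),
        "m_t": ParameterPrior("m_t", 0.1, 0.9),
        "t_d": ParameterPrior("t_d", 7.0, 30.0),
    }
    for name in ("alpha_es", "alpha_ei", "alpha_ls", "alpha_li"):
        priors[name] = ParameterPrior(name, 0.0, 1.0)
    for name in ("beta_alp", "beta_oc", "beta_ars"):
        priors[name] = ParameterPrior(name, 0.0, 2.0)
    for name in ("n_alp", "n_oc", "n_ars"):
        priors[name] = ParameterPrior(name, 0.5, 3.0)
    for name in REGISTRY:
        if name.startswith("k_"):
            priors[name] = ParameterPrior(name, 0.1, 10.0, scale="log")
    return priors


#: per-study relevant parameter subsets. A study exposes the membership
#: anchors of the signals it varies, the output-level centers its conditions
#: can reach, the dynamics parameters of the phases its markers probe, and
#: its own marker-mapping parameters.
_STUDY_SUBSETS: dict[int, tuple[str, ...]] = {
    1: (
        "p_ms", "p_md", "p_es", "p_ef",
        "m_t", "t_d", "alpha_es", "alpha_ei",
        "beta_alp", "n_alp", "k_alp_1",
    ),
    2: (
        "p_ms", "p_md", "p_ef", "p_ls",
        "m_t", "t_d", "alpha_es", "alpha_ls", "alpha_li",
        "beta_alp", "n_alp", "k_alp_2", "beta_oc", "n_oc", "k_oc_2",
    ),
    3: (
        "p_es", "p_ef", "p_evf", "p_ls", "p_lf",
        "m_t", "t_d", "alpha_es", "alpha_ei", "alpha_ls", "alpha_li",
        "beta_alp", "n_alp", "k_alp_3", "beta_ars", "n_ars", "k_ars_3",
    ),
    4: (
        "p_es", "p_ef", "p_evf", "p_ls", "p_lf",
        "m_t", "t_d", "alpha_es", "alpha_ei", "alpha_ls", "alpha_li",
        "beta_alp", "n_alp", "k_alp_4", "beta_ars", "n_ars", "k_ars_4",
    ),
    5: (
        "p_8f", "p_1bs", "p_1bie", "p_ef", "p_evf",
        "m_t", "t_d", "alpha_es",
        "beta_alp", "n_alp", "k_alp_5",
    ),
}


def relevant_parameters(studies: int | list[int] | None = None) -> tuple[str, ...]:
    """Free-parameter names exposed when calibrating the given studies.

    ``None`` (or all five studies) yields the full 30-entry registry, in
    registry order.
    """
    if studies is None:
        return REGISTRY
    if isinstance(studies, int):
        studies = [studies]
    if sorted(set(studies)) == [1, 2, 3, 4, 5]:
        return REGISTRY
    names: set[str] = set()
    for s in studies:
        if s not in _STUDY_SUBSETS:
            raise ParameterError(f"unknown study id {s}")
        names.update(_STUDY_SUBSETS[s])
    return tuple(n for n in REGISTRY if n in names)
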