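"""Differentiation dynamics: from fuzzy rates to maturity and markers.

The controller's crisp outputs ``f_e`` and ``f_l`` (0.5 = physiological)
are scaled into physical rates

    r_e = r_0 * S(f_e),   r_l = r_0 * S(f_l),   r_0 = 1 / T_d,

where S is piecewise linear through S(0.5) = 1 with separate stimulatory
(x > 0.5) and inhibitory (x <= 0.5) slopes, clamped at zero from below
(a differentiation rate cannot be negative).

Maturity, the state variable in [0, 1] tracking progression from MSC to
mature osteoblast, accumulates the early rate until the early phase ends at
T_e = M_t * T_d and the late rate afterwards:

    maturity(T) = T * r_e                      for T <= T_e
                = T_e * r_e + (T - T_e) * r_l  for T >  T_e

Under piecewise-constant input schedules the rates are constant within each
segment, so the forward-Euler accumulation used here is exact up to grid
alignment of the segment edges and T_e.

Markers map maturity to measured quantities:

    y_i = (x + beta_i)^(n_i) * k_{i,j}

with x = min(maturity, M_t) for ALP (an early marker that saturates once
the early phase completes) and x = maturity for OC and ARS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .controller import CellInputs, ControllerParams, infer_rates
from .errors import DesignError, FuzzyConfigError, InputError
from .params import ModelParameters

__all__ = [
    "DynamicsParams",
    "CellState",
    "Segment",
    "Schedule",
    "scale_rate",
    "physical_rates",
    "maturity_closed_form",
    "integrate_maturity",
    "marker_value",
    "simulate_study",
]

MARKERS = ("ALP", "OC", "ARS")


@dataclass(frozen=True)
class DynamicsParams:
    """Maturation threshold, differentiation time and rate sensitivities.

    ``m_t`` in (0, 1); ``t_d`` in days; the four alphas are dimensionless
    sensitivities of the early/late rates to stimulatory (s) and inhibitory
    (i) signals. ``stimulatory_branch_high`` selects whether the
    stimulatory slope applies above 0.5 (default, matching the narrative
    that a larger alpha_es speeds maturation) or below (the transposed
    printed form).
    """

    m_t: float = 0.4
    t_d: float = 21.0
    alpha_es: float = 0.5
    alpha_ei: float = 0.5
    alpha_ls: float = 0.5
    alpha_li: float = 0.5
    stimulatory_branch_high: bool = True
    phase_switch: str = "time"  # "time" (T_e = M_t*T_d) | "maturity" (M >= M_t)

    def __post_init__(self) -> None:
        if self.phase_switch not in ("time", "maturity"):
            raise InputError(f"unknown phase_switch {self.phase_switch!r}")
        if not 0.0 < self.m_t < 1.0:
            raise InputError(f"m_t must lie in (0, 1), got {self.m_t}")
        if self.t_d <= 0.0:
            raise InputError(f"t_d must be > 0, got {self.t_d}")
        for name in ("alpha_es", "alpha_ei", "alpha_ls", "alpha_li"):
            if getattr(self, name) < 0.0:
                raise InputError(f"{name} must be >= 0")

    @classmethod
    def from_model(cls, theta: ModelParameters) -> "DynamicsParams":
        return cls(
            m_t=theta.m_t, t_d=theta.t_d,
            alpha_es=theta.alpha_es, alpha_ei=theta.alpha_ei,
            alpha_ls=theta.alpha_ls, alpha_li=theta.alpha_li,
        )

    @property
    def t_e_days(self) -> float:
        """End of the early phase, T_e = M_t * T_d [days]."""
        return self.m_t * self.t_d


@dataclass(frozen=True)
class CellState:
    maturity: float
    t: float  # elapsed time [hours]

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturity <= 1.0:
            raise InputError(f"maturity must lie in [0, 1], got {self.maturity}")
        if self.t < 0.0:
            raise InputError(f"t must be >= 0, got {self.t}")


@dataclass(frozen=True)
class Segment:
    t_start: float  # hours
    t_end: float  # hours
    inputs: CellInputs


@dataclass(frozen=True)
class Schedule:
    """Contiguous piecewise-constant input segments covering [0, horizon]."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise DesignError("schedule must have at least one segment")
        if self.segments[0].t_start != 0.0:
            raise DesignError("schedule must start at t = 0")
        prev_end = 0.0
        for seg in self.segments:
            if seg.t_start != prev_end:
                raise DesignError(
                    f"segments must be contiguous; gap/overlap at t={seg.t_start} h"
                )
            if seg.t_end <= seg.t_start:
                raise DesignError("segment must have positive duration")
            prev_end = seg.t_end

    @property
    def horizon(self) -> float:
        return self.segments[-1].t_end

    @classmethod
    def constant(cls, inputs: CellInputs, horizon_h: float) -> "Schedule":
        return cls((Segment(0.0, float(horizon_h), inputs),))

    @classmethod
    def pulse(
        cls,
        inputs: CellInputs,
        duration_h: float,
        horizon_h: float,
        baseline: CellInputs | None = None,
    ) -> "Schedule":
        """Apply ``inputs`` for ``duration_h`` then revert to the baseline
        (physiological medium: Mg 0.8 mM, cytokines 0 ng/ml)."""
        if baseline is None:
            baseline = CellInputs.physiological()
        if duration_h >= horizon_h:
            return cls.constant(inputs, horizon_h)
        return cls(
            (
                Segment(0.0, float(duration_h), inputs),
                Segment(float(duration_h), float(horizon_h), baseline),
            )
        )


# ---------------------------------------------------------------------------
# rate scaling
# ---------------------------------------------------------------------------

def scale_rate(
    x: float, alpha_s: float, alpha_i: float, stimulatory_branch_high: bool = True
) -> float:
    """Piecewise-linear scaling S(x) of a fuzzy rate, S(0.5) = 1.

    The branch carrying ``alpha_s`` amplifies deviations above the
    physiological rate and the ``alpha_i`` branch attenuates those below it
    (or vice versa with ``stimulatory_branch_high=False``). Clamped at 0.
    """
    if not 0.0 <= x <= 1.0:
        raise InputError(f"fuzzy rate must lie in [0, 1], got {x}")
    if stimulatory_branch_high:
        alpha = alpha_s if x > 0.5 else alpha_i
    else:
        alpha = alpha_i if x > 0.5 else alpha_s
    return max(0.0, 2.0 * alpha * (x - 0.5) + 1.0)


def physical_rates(
    f_e: float, f_l: float, dp: DynamicsParams
) -> tuple[float, float]:
    """Physical early/late rates [1/day]: r = S(f) / T_d."""
    r0 = 1.0 / dp.t_d
    r_e = r0 * scale_rate(
        f_e, dp.alpha_es, dp.alpha_ei, dp.stimulatory_branch_high
    )
    r_l = r0 * scale_rate(
        f_l, dp.alpha_ls, dp.alpha_li, dp.stimulatory_branch_high
    )
    return r_e, r_l


def maturity_closed_form(
    t_days: float, r_e: float, r_l: float, m_t: float, t_d: float
) -> float:
    """Maturity at ``t_days`` under constant rates (clamped to [0, 1])."""
    t_e = m_t * t_d
    if t_days <= t_e:
        m = t_days * r_e
    else:
        m = t_e * r_e + (t_days - t_e) * r_l
    return min(max(m, 0.0), 1.0)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_maturity(
    schedule: Schedule,
    cp: ControllerParams,
    dp: DynamicsParams,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler maturity trajectory over a piecewise-constant schedule.

    ``dt`` is the step in hours. The controller is re-evaluated once per
    segment (rates depend only on the inputs); within a segment the active
    rate is the early one during the early phase and the late one
    afterwards. The phase ends at T_e = M_t * T_d by default, or when the
    accumulated maturity reaches M_t with ``phase_switch="maturity"``.
    Returns (times_h, maturity), maturity clamped to [0, 1].
    """
    if dt <= 0.0:
        raise InputError(f"dt must be > 0, got {dt}")
    shortest = min(s.t_end - s.t_start for s in schedule.segments)
    if dt > shortest:
        raise DesignError(
            f"dt={dt} h exceeds the shortest schedule segment ({shortest} h)"
        )
    horizon = schedule.horizon
    n_steps = int(round(horizon / dt))
    times = np.arange(n_steps + 1) * dt
    step_starts = times[:-1]

    # per-segment physical rates, expanded to per-step early/late arrays
    r_early = np.empty(n_steps)
    r_late = np.empty(n_steps)
    for seg in schedule.segments:
        mask = (step_starts >= seg.t_start) & (step_starts < seg.t_end)
        if not np.any(mask):
            continue
        f = infer_rates(seg.inputs, cp)
        r_e, r_l = physical_rates(f.f_e, f.f_l, dp)
        r_early[mask] = r_e
        r_late[mask] = r_l

    if dp.phase_switch == "time":
        t_e_h = dp.t_e_days * 24.0
        rates = np.where(step_starts < t_e_h, r_early, r_late)
        maturity = np.concatenate(([0.0], np.cumsum(rates * dt / 24.0)))
    else:  # maturity-based switching: state-dependent, stepped sequentially
        maturity = np.zeros(n_steps + 1)
        m = 0.0
        for i in range(n_steps):
            r = r_early[i] if m < dp.m_t else r_late[i]
            m += r * dt / 24.0
            maturity[i + 1] = m
    np.clip(maturity, 0.0, 1.0, out=maturity)
    return times, maturity


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def marker_value(
    maturity: float,
    marker: str,
    study: int,
    theta: ModelParameters,
) -> float:
    """Marker readout y = (x + beta)^n * k for one maturity value.

    ALP is conditioned on the early phase: x = min(maturity, M_t); the late
    markers OC and ARS track maturity over its whole range.
    """
    marker = marker.upper()
    if marker not in MARKERS:
        raise InputError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    if not 0.0 <= maturity <= 1.0:
        raise InputError(f"maturity must lie in [0, 1], got {maturity}")
    x = min(maturity, theta.m_t) if marker == "ALP" else maturity
    k = theta.correction_factor(marker, study)
    return (x + theta.beta(marker)) ** theta.n(marker) * k


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

def simulate_study(design, theta: ModelParameters, dt: float = 1.0) -> list:
    """Predict every (condition, marker, day) item of a study design.

    For fold-over-control designs each value is divided by the control
    condition's value at the same marker and day. Returns
    :class:`~osteofuzz.studies.MeasurementItem` records with sd = 0.
    """
    from .studies import MeasurementItem  # deferred: studies imports dynamics

    cp = theta.controller()
    dp = DynamicsParams.from_model(theta)

    maturity_at: dict[tuple[str, float], float] = {}
    for label, schedule in design.conditions:
        times, traj = integrate_maturity(schedule, cp, dp, dt=dt)
        for marker, day in design.measurements:
            t_h = day * 24.0
            if t_h > schedule.horizon + 1e-9:
                raise DesignError(
                    f"{design.study_id}/{label}: day {day} beyond schedule horizon"
                )
            maturity_at[(label, day)] = float(np.interp(t_h, times, traj))

    relative = design.normalization == "fold-over-control"
    if relative and design.control not in {c[0] for c in design.conditions}:
        raise DesignError(
            f"study {design.study_id}: control {design.control!r} missing"
        )

    items = []
    inputs_by_label = {label: sched.segments[0].inputs for label, sched in design.conditions}
    for label, schedule in design.conditions:
        for marker, day in design.measurements:
            value = marker_value(maturity_at[(label, day)], marker, design.study_id, theta)
            if relative:
                ref = marker_value(
                    maturity_at[(design.control, day)], marker, design.study_id, theta
                )
                value = value / ref
            items.append(
                MeasurementItem(
                    study_id=design.study_id,
                    marker=marker,
                    day=day,
                    condition=label,
                    value=value,
                    sd=0.0,
                    inputs=inputs_by_label[label],
                    normalization=design.normalization,
                )
            )
    return items
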