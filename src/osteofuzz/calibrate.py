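"""Parameter estimation by repeated differential evolution.

The goodness of fit of one simulated value S against an empirical value E
is the clamped normalized absolute difference

    fitness = clamp(1 - |E - S| / E, 0, 1),

which is 1 for a perfect fit and 0 once the deviation reaches the
empirical value itself. The objective is the arithmetic mean over all
measurement items.

Because a single DE run can settle in different optima, calibration is
repeated over many independently seeded runs; the inferred value of each
parameter is the mean of the per-run bests, and a half-split check declares
convergence when the means of the first and second halves of the runs agree
within a tolerance expressed as a fraction of the prior length.
Log-scaled parameters (the correction factors) are searched in log10 space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .errors import DataError, InputError, ParameterError
from .params import ModelParameters, ParameterPrior, default_priors, relevant_parameters
from .studies import MeasurementItem, StudyDesign, builtin_designs
from .dynamics import simulate_study

__all__ = [
    "DESettings",
    "CalibrationRun",
    "CalibrationSummary",
    "fitness_item",
    "objective",
    "make_objective",
    "run_de",
    "calibrate_repeated",
]


@dataclass(frozen=True)
class DESettings:
    """Differential-evolution settings (rand/1/bin).

    ``pop`` is the total population size; scipy's multiplier is derived
    from it and the problem dimension.
    """

    pop: int = 45
    generations: int = 200
    f: float = 0.8  # mutation weight
    cr: float = 0.9  # crossover probability

    def popsize_multiplier(self, dim: int) -> int:
        return max(1, round(self.pop / dim))


@dataclass(frozen=True)
class CalibrationRun:
    best: dict[str, float]
    fitness: float
    seed: int


@dataclass
class CalibrationSummary:
    table: pd.DataFrame  # parameter, mean, sd, half1_mean, half2_mean, prior_length
    runs: list[CalibrationRun]
    converged: bool
    tolerance: float

    def inferred(self) -> dict[str, float]:
        return dict(zip(self.table["parameter"], self.table["mean"]))


def fitness_item(E: float, S: float, clamped: bool = True) -> float:
    """Per-item fitness 1 - |E - S| / E, clamped to [0, 1].

    With ``clamped=False`` the raw discrepancy |E - S| / E is returned
    instead (for inspection; larger is then worse).
    """
    if E <= 0.0:
        raise InputError(f"empirical value must be > 0, got {E}")
    discrepancy = abs(E - S) / E
    if not clamped:
        return discrepancy
    return min(1.0, max(0.0, 1.0 - discrepancy))


def objective(
    theta: ModelParameters,
    data: list[MeasurementItem],
    designs: dict[int, StudyDesign] | None = None,
    dt: float = 1.0,
    per_item: bool = False,
):
    """Mean fitness of ``theta`` against a measurement table.

    Simulates every study referenced by the data and matches items by
    (study, condition, marker, day). With ``per_item=True`` also returns
    the per-item fitness mapping (the per-bar values reported alongside
    study figures).
    """
    if not data:
        raise DataError("empty measurement table")
    if designs is None:
        designs = builtin_designs()
    needed = sorted({item.study_id for item in data})
    predictions: dict[tuple, float] = {}
    for study_id in needed:
        if study_id not in designs:
            raise DataError(f"data references unknown study {study_id}")
        for pred in simulate_study(designs[study_id], theta, dt=dt):
            predictions[pred.key] = pred.value
    scores: dict[tuple, float] = {}
    for item in data:
        if item.key not in predictions:
            raise DataError(f"unresolvable measurement item {item.key}")
        scores[item.key] = fitness_item(item.value, predictions[item.key])
    mean = float(np.mean(list(scores.values())))
    if per_item:
        return mean, scores
    return mean


# ---------------------------------------------------------------------------
# search-space transforms
# ---------------------------------------------------------------------------

def _to_search(value: float, prior: ParameterPrior) -> float:
    return math.log10(value) if prior.scale == "log" else value


def _from_search(value: float, prior: ParameterPrior) -> float:
    return 10.0**value if prior.scale == "log" else value


def _bounds(priors: list[ParameterPrior]) -> list[tuple[float, float]]:
    return [
        (_to_search(p.lower, p), _to_search(p.upper, p)) for p in priors
    ]


def make_objective(
    data: list[MeasurementItem],
    free_names: tuple[str, ...] | list[str],
    base_theta: ModelParameters,
    designs: dict[int, StudyDesign] | None = None,
    dt: float = 1.0,
):
    """Vector objective over the free parameters (others fixed at base).

    Returns ``f(search_vector) -> mean fitness`` where log-scaled entries
    of the vector are in log10 units. Search points violating a parameter
    ordering constraint (e.g. p_md <= p_ms) score 0.
    """
    priors_all = default_priors()
    priors = [priors_all[name] for name in free_names]

    def f(vec) -> float:
        updates = {
            name: _from_search(float(v), prior)
            for name, prior, v in zip(free_names, priors, vec)
        }
        try:
            theta = base_theta.replace(**updates)
            theta.controller()  # surfaces ordering violations early
        except Exception:
            return 0.0
        return objective(theta, data, designs=designs, dt=dt)

    return f


def run_de(
    objective_fn,
    priors: list[ParameterPrior],
    settings: DESettings,
    seed: int,
) -> CalibrationRun:
    """One differential-evolution maximization of the fitness objective."""
    bounds = _bounds(priors)
    result = differential_evolution(
        lambda v: 1.0 - objective_fn(v),
        bounds=bounds,
        strategy="rand1bin",
        maxiter=settings.generations,
        popsize=settings.popsize_multiplier(len(bounds)),
        mutation=settings.f,
        recombination=settings.cr,
        seed=seed,
        tol=0.0,
        polish=False,
        init="latinhypercube",
    )
    best = {
        p.name: _from_search(float(v), p) for p, v in zip(priors, result.x)
    }
    return CalibrationRun(best=best, fitness=1.0 - float(result.fun), seed=seed)


def calibrate_repeated(
    data: list[MeasurementItem],
    free_names: tuple[str, ...] | list[str] | None = None,
    base_theta: ModelParameters | None = None,
    settings: DESettings | None = None,
    n_runs: int = 20,
    base_seed: int = 0,
    tolerance: float = 0.05,
    designs: dict[int, StudyDesign] | None = None,
    dt: float = 1.0,
    progress=None,
) -> CalibrationSummary:
    """Repeated DE calibration with the half-split convergence check.

    Run ``i`` uses seed ``base_seed + i``. The convergence flag is true
    when, for every parameter, the means of the first and second halves of
    the runs (floor/ceil split for odd ``n_runs``) differ by at most
    ``tolerance`` times the prior length, measured on the search axis.
    """
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2 (halves undefined otherwise)")
    if base_theta is None:
        base_theta = ModelParameters()
    if settings is None:
        settings = DESettings()
    if free_names is None:
        free_names = relevant_parameters(sorted({it.study_id for it in data}))
    priors_all = default_priors()
    priors = [priors_all[name] for name in free_names]
    objective_fn = make_objective(
        data, free_names, base_theta, designs=designs, dt=dt
    )

    runs: list[CalibrationRun] = []
    for i in range(n_runs):
        run = run_de(objective_fn, priors, settings, seed=base_seed + i)
        runs.append(run)
        if progress is not None:
            progress(run)

    # per-parameter statistics on the search axis
    half = n_runs // 2
    rows = []
    converged = True
    for prior in priors:
        values = np.array(
            [_to_search(run.best[prior.name], prior) for run in runs]
        )
        h1, h2 = values[:half].mean(), values[half:].mean()
        gap = abs(h1 - h2) / prior.length
        if gap > tolerance:
            converged = False
        rows.append(
            {
                "parameter": prior.name,
                "mean": float(
                    _from_search(values.mean(), prior)
                    if prior.scale == "log"
                    else values.mean()
                ),
                "sd": float(values.std(ddof=1)) if n_runs > 1 else 0.0,
                "half1_mean": float(_from_search(h1, prior)),
                "half2_mean": float(_from_search(h2, prior)),
                "half_gap_fraction": float(gap),
                "prior_length": prior.length,
            }
        )
    table = pd.DataFrame(rows)
    return CalibrationSummary(
        table=table, runs=runs, converged=converged, tolerance=tolerance
    )
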