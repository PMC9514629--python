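"""Parameter sensitivity: LSSP and SSIP protocols.

LSSP (large-scale simultaneous perturbation) perturbs study-relevant
parameters together by +/-50% of their inferred values, sampling the
two-level combinations with an orthogonal fractional factorial design and
ranking parameters by their ANOVA main-effect contribution to the simulated
outputs. SSIP (small-scale individual perturbation) perturbs one parameter
at a time by +/-15% and reports, per measurement item, the spread of the
outputs and the mean percentage change.

The factorial designs are built from Sylvester-Hadamard matrices: dropping
the all-ones column of H(2^m) yields a balanced, orthogonal two-level
design of resolution III for up to 2^m - 1 factors; a fold-over doubles the
runs and raises the resolution to IV (main effects unconfounded with
two-factor interactions). On these orthogonal designs the ANOVA main-effect
sum of squares reduces exactly to the contrast N * (effect/2)^2, which is
what the ranking uses; per-item responses are normalized by their total
variation so the ranking is invariant to rescaling any output by a positive
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .errors import DesignError
from .params import ModelParameters, default_priors, relevant_parameters
from .studies import StudyDesign, builtin_designs
from .dynamics import simulate_study
from .calibrate import objective as mean_fitness_objective

__all__ = ["ffd_design", "lssp", "ssip", "SensitivityReport"]


@dataclass
class SensitivityReport:
    lssp: pd.DataFrame | None = None  # parameter, effect score, rank per study
    ssip: pd.DataFrame | None = None  # per-(parameter, item) variations


def ffd_design(n_params: int, resolution: int = 4) -> np.ndarray:
    """Two-level fractional factorial design matrix with +/-1 entries.

    Resolution III uses the non-constant columns of the smallest Sylvester
    Hadamard matrix with at least ``n_params + 1`` columns; resolution IV is
    its fold-over. Columns are balanced and mutually orthogonal.
    """
    if n_params < 2:
        raise DesignError("need at least 2 parameters for a factorial design")
    if resolution not in (3, 4):
        raise DesignError(f"unsupported resolution {resolution}; use 3 or 4")
    m = 1
    while 2**m - 1 < n_params:
        m += 1
    H = hadamard(2**m)
    design = H[:, 1 : n_params + 1].astype(float)
    if resolution == 4:
        design = np.vstack([design, -design])
    return design


_EPS = 1e-3


def _repair_orderings(values: dict[str, float], clip_log: list[str]) -> dict[str, float]:
    """Project a perturbed parameter dict onto the feasible ordering region.

    Large joint perturbations can break the ordering constraints between
    membership anchors (e.g. p_ef pushed above p_evf); offenders are moved
    by the minimal epsilon that restores feasibility and logged.
    """
    v = dict(values)

    def adjust(name: str, new: float) -> None:
        if v[name] != new:
            v[name] = new
            clip_log.append(name)

    adjust("p_es", min(max(v["p_es"], _EPS), 0.5 - _EPS))
    adjust("p_ls", min(max(v["p_ls"], _EPS), 0.5 - _EPS))
    adjust("p_ef", min(max(v["p_ef"], 0.5 + _EPS), 1.0 - 3 * _EPS))
    adjust("p_lf", min(max(v["p_lf"], 0.5 + _EPS), 1.0 - _EPS))
    adjust("p_evf", min(max(v["p_evf"], v["p_ef"] + _EPS), 1.0 - _EPS))
    adjust("p_md", max(v["p_md"], v["p_ms"] + _EPS))
    adjust("p_8f", min(max(v["p_8f"], 0.11), 99.9))
    adjust("p_1bs", min(max(v["p_1bs"], 0.11), 99.0))
    adjust("p_1bie", max(v["p_1bie"], v["p_1bs"] * (1.0 + _EPS)))
    return v


def _perturbed(
    theta: ModelParameters,
    names: list[str],
    factors: np.ndarray,
    clip_log: list[str],
) -> ModelParameters:
    """theta with each named parameter multiplied by its factor, clipped to
    the prior bounds and repaired to respect ordering constraints (all
    adjusted names appended to ``clip_log``)."""
    priors = default_priors()
    updates = {}
    for name, factor in zip(names, factors):
        value = getattr(theta, name) * factor
        prior = priors[name]
        clipped = min(max(value, prior.lower), prior.upper)
        if clipped != value:
            clip_log.append(name)
        updates[name] = clipped
    full = theta.as_dict()
    full.update(updates)
    return ModelParameters(**_repair_orderings(full, clip_log))


def _responses(
    theta: ModelParameters, design: StudyDesign, dt: float
) -> tuple[list[tuple], np.ndarray]:
    preds = simulate_study(design, theta, dt=dt)
    return [p.key for p in preds], np.array([p.value for p in preds])


def lssp(
    theta: ModelParameters,
    designs: dict[int, StudyDesign] | None = None,
    data=None,
    magnitude: float = 0.5,
    resolution: int = 4,
    params: tuple[str, ...] | None = None,
    dt: float = 1.0,
    top: int = 5,
) -> pd.DataFrame:
    """LSSP ranking, one block of rows per study.

    Parameters default to each study's relevant subset; levels -1/+1 map to
    theta * (1 -/+ magnitude). Returns a tidy frame with columns study,
    parameter, effect_score (normalized main-effect share averaged over the
    study's measurement items), rank and top5 flag; when ``data`` is given
    an auxiliary mean-fitness effect column is included.
    """
    if designs is None:
        designs = builtin_designs()
    frames = []
    for study_id in sorted(designs):
        names = list(
            params if params is not None else relevant_parameters(study_id)
        )
        if len(names) < 2:
            raise DesignError("LSSP needs at least two parameters")
        X = ffd_design(len(names), resolution=resolution)
        n_runs = X.shape[0]
        clip_log: list[str] = []
        Y = []
        fit = []
        study_data = (
            [it for it in data if it.study_id == study_id] if data else None
        )
        for row in X:
            theta_r = _perturbed(
                theta, names, 1.0 + magnitude * row, clip_log
            )
            _, y = _responses(theta_r, designs[study_id], dt)
            Y.append(y)
            if study_data:
                fit.append(
                    mean_fitness_objective(
                        theta_r, study_data, designs=designs, dt=dt
                    )
                )
        Y = np.array(Y)  # runs x items

        # main effects by orthogonal contrast: effect = X^T y / n_runs * 2
        effects = X.T @ Y / n_runs * 2.0  # params x items
        ss = n_runs * (effects / 2.0) ** 2
        total = ss.sum(axis=0)
        share = np.divide(
            ss, total, out=np.zeros_like(ss), where=total > 0
        )  # per-item normalized contribution
        score = share.mean(axis=1)
        order = np.argsort(-score, kind="stable")
        rank = np.empty(len(names), dtype=int)
        rank[order] = np.arange(1, len(names) + 1)
        frame = pd.DataFrame(
            {
                "study_id": study_id,
                "parameter": names,
                "effect_score": score,
                "rank": rank,
                "top5": rank <= top,
                "clipped": [n in clip_log for n in names],
            }
        )
        if study_data:
            fit_arr = np.array(fit)
            fit_effect = X.T @ fit_arr / n_runs * 2.0
            frame["fitness_effect"] = np.abs(fit_effect)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def ssip(
    theta: ModelParameters,
    designs: dict[int, StudyDesign] | None = None,
    magnitude: float = 0.15,
    params: tuple[str, ...] | None = None,
    dt: float = 1.0,
) -> pd.DataFrame:
    """One-at-a-time +/-``magnitude`` perturbations around ``theta``.

    For every (parameter, measurement item) pair reports the unperturbed
    value, the two perturbed values, their standard deviation (the SSIP
    error bar) and the mean absolute percentage change.
    """
    if designs is None:
        designs = builtin_designs()
    rows = []
    for study_id in sorted(designs):
        design = designs[study_id]
        keys, y0 = _responses(theta, design, dt)
        names = params if params is not None else relevant_parameters(study_id)
        for name in names:
            clip_log: list[str] = []
            y_lo = _responses(
                _perturbed(theta, [name], np.array([1.0 - magnitude]), clip_log),
                design,
                dt,
            )[1]
            y_hi = _responses(
                _perturbed(theta, [name], np.array([1.0 + magnitude]), clip_log),
                design,
                dt,
            )[1]
            pct = 0.5 * (np.abs(y_lo - y0) + np.abs(y_hi - y0)) / y0 * 100.0
            sd = np.std(np.vstack([y_lo, y_hi]), axis=0, ddof=0)
            for key, v0, vlo, vhi, s, p in zip(keys, y0, y_lo, y_hi, sd, pct):
                rows.append(
                    {
                        "study_id": key[0],
                        "condition": key[1],
                        "marker": key[2],
                        "day": key[3],
                        "parameter": name,
                        "value": v0,
                        "value_minus": vlo,
                        "value_plus": vhi,
                        "sd": s,
                        "pct_change": p,
                        "clipped": bool(clip_log),
                    }
                )
    return pd.DataFrame(rows)
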