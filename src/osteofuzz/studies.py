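"""Built-in cell-culture study designs and the synthetic-data generator.

Five published cell-culture experiments anchor the model's calibration:

1. Mg2+ at 0.08 / 0.8 / 8 mM, ALP at days 3 and 7.
2. Mg2+ at 0.8 / 5 mM, ALP at day 7 and OC at day 21.
3. IL-10 (0 / 0.1 / 1 / 10 ng/ml) and TNF-alpha (0 / 1 / 10 / 100 ng/ml)
   applied for 48 h; ALP at day 14, ARS at day 21.
4. IL-10 (0 / 0.1 / 1 / 10 / 100 ng/ml) applied continuously (long-term
   exposure); ALP at day 3 and ARS at day 9, reported as fold over an
   undifferentiated control.
5. IL-8 (0 / 10 / 100 ng/ml), IL-1beta (0 / 10 ng/ml) and the combined
   IL-8 100 + IL-1beta 10 condition; ALP at day 9.

The original reports publish their measurements only as figure bars, so no
empirical values ship with the package. Instead, a generator produces
synthetic measurement tables from any ground-truth parameter set under the
same designs, with multiplicative lognormal noise of a chosen coefficient
of variation — the substrate for parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .controller import CellInputs
from .dynamics import Schedule, simulate_study
from .errors import DesignError, SchemaError
from .params import ModelParameters

__all__ = [
    "StudyDesign",
    "MeasurementItem",
    "builtin_designs",
    "generate_synthetic",
    "read_measurements",
    "write_measurements",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "study_id", "marker", "day", "condition",
    "mg_mM", "tnf_ng_ml", "il10_ng_ml", "il8_ng_ml", "il1b_ng_ml",
    "exposure_h", "value", "sd", "normalization",
]


@dataclass(frozen=True)
class MeasurementItem:
    """One (study, marker, day, condition) record, empirical or simulated."""

    study_id: int
    marker: str
    day: float
    condition: str
    value: float
    sd: float
    inputs: CellInputs | None = None
    normalization: str = "absolute"

    def __post_init__(self) -> None:
        if self.value <= 0.0:
            raise SchemaError(
                f"{self.study_id}/{self.condition}/{self.marker}: value must be > 0"
            )
        if self.sd < 0.0:
            raise SchemaError(
                f"{self.study_id}/{self.condition}/{self.marker}: sd must be >= 0"
            )

    @property
    def key(self) -> tuple[int, str, str, float]:
        return (self.study_id, self.condition, self.marker, self.day)


@dataclass(frozen=True)
class StudyDesign:
    study_id: int
    conditions: tuple[tuple[str, Schedule], ...]
    measurements: tuple[tuple[str, float], ...]  # (marker, day)
    normalization: str = "absolute"
    control: str = ""

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise DesignError(f"study {self.study_id}: duplicate condition labels")
        if self.control and self.control not in labels:
            raise DesignError(
                f"study {self.study_id}: control {self.control!r} not a condition"
            )
        if self.normalization not in ("absolute", "fold-over-control"):
            raise DesignError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "fold-over-control" and not self.control:
            raise DesignError(
                f"study {self.study_id}: relative design needs a control condition"
            )
        for marker, day in self.measurements:
            if day <= 0:
                raise DesignError(f"study {self.study_id}: day must be > 0")


def _days(d: float) -> float:
    return d * 24.0


def builtin_designs() -> dict[int, StudyDesign]:
    """The five built-in study designs, keyed by study id."""
    physio = CellInputs.physiological()

    s1 = StudyDesign(
        study_id=1,
        conditions=tuple(
            (f"Mg_{mg:g}", Schedule.constant(CellInputs(mg=mg), _days(7)))
            for mg in (0.08, 0.8, 8.0)
        ),
        measurements=(("ALP", 3.0), ("ALP", 7.0)),
        control="Mg_0.08",
    )

    s2 = StudyDesign(
        study_id=2,
        conditions=tuple(
            (f"Mg_{mg:g}", Schedule.constant(CellInputs(mg=mg), _days(21)))
            for mg in (0.8, 5.0)
        ),
        measurements=(("ALP", 7.0), ("OC", 21.0)),
        control="Mg_0.8",
    )

    # 48-h cytokine application, then physiological medium
    s3_conditions: list[tuple[str, Schedule]] = [
        ("control", Schedule.constant(physio, _days(21)))
    ]
    for c in (0.1, 1.0, 10.0):
        s3_conditions.append(
            (
                f"IL10_{c:g}",
                Schedule.pulse(
                    CellInputs(il10=c, il10_exposure=48.0), 48.0, _days(21)
                ),
            )
        )
    for c in (1.0, 10.0, 100.0):
        s3_conditions.append(
            (f"TNF_{c:g}", Schedule.pulse(CellInputs(tnf=c), 48.0, _days(21)))
        )
    s3 = StudyDesign(
        study_id=3,
        conditions=tuple(s3_conditions),
        measurements=(("ALP", 14.0), ("ARS", 21.0)),
        control="control",
    )

    # continuous (long-term) IL-10 exposure; fold over undifferentiated control
    s4_horizon = _days(9)
    s4_conditions: list[tuple[str, Schedule]] = [
        ("ctr", Schedule.constant(physio, s4_horizon))
    ]
    for c in (0.0, 0.1, 1.0, 10.0, 100.0):
        s4_conditions.append(
            (
                f"IL10_{c:g}",
                Schedule.constant(
                    CellInputs(il10=c, il10_exposure=s4_horizon), s4_horizon
                ),
            )
        )
    s4 = StudyDesign(
        study_id=4,
        conditions=tuple(s4_conditions),
        measurements=(("ALP", 3.0), ("ARS", 9.0)),
        normalization="fold-over-control",
        control="ctr",
    )

    # continuous IL-8 / IL-1beta application until the measurement day
    s5_horizon = _days(9)
    s5_conditions = (
        ("control", Schedule.constant(physio, s5_horizon)),
        ("IL8_10", Schedule.constant(CellInputs(il8=10.0), s5_horizon)),
        ("IL8_100", Schedule.constant(CellInputs(il8=100.0), s5_horizon)),
        ("IL1b_10", Schedule.constant(CellInputs(il1b=10.0), s5_horizon)),
        (
            "IL8_100+IL1b_10",
            Schedule.constant(CellInputs(il8=100.0, il1b=10.0), s5_horizon),
        ),
    )
    s5 = StudyDesign(
        study_id=5,
        conditions=s5_conditions,
        measurements=(("ALP", 9.0),),
        control="control",
    )

    return {d.study_id: d for d in (s1, s2, s3, s4, s5)}


def generate_synthetic(
    theta_true: ModelParameters,
    noise_cv: float = 0.0,
    seed: int = 0,
    designs: dict[int, StudyDesign] | None = None,
    dt: float = 1.0,
) -> list[MeasurementItem]:
    """Simulate all designs under ``theta_true`` and add measurement noise.

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``noise_cv`` (the reported per-bar standard deviation is
    ``noise_cv * value``). ``noise_cv=0`` returns the model predictions
    exactly. Deterministic for a fixed ``seed``.
    """
    if noise_cv < 0.0:
        raise SchemaError(f"noise_cv must be >= 0, got {noise_cv}")
    if designs is None:
        designs = builtin_designs()
    rng = np.random.default_rng(seed)
    items: list[MeasurementItem] = []
    for study_id in sorted(designs):
        for pred in simulate_study(designs[study_id], theta_true, dt=dt):
            if noise_cv == 0.0:
                value = pred.value
            else:
                sigma2 = math.log(1.0 + noise_cv**2)
                factor = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2))
                value = pred.value * factor
            items.append(replace(pred, value=value, sd=noise_cv * pred.value))
    return items


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_measurements(items: list[MeasurementItem], path) -> None:
    rows = []
    for item in items:
        inp = item.inputs or CellInputs.physiological()
        rows.append(
            {
                "study_id": item.study_id,
                "marker": item.marker,
                "day": item.day,
                "condition": item.condition,
                "mg_mM": inp.mg,
                "tnf_ng_ml": inp.tnf,
                "il10_ng_ml": inp.il10,
                "il8_ng_ml": inp.il8,
                "il1b_ng_ml": inp.il1b,
                "exposure_h": inp.il10_exposure,
                "value": item.value,
                "sd": item.sd,
                "normalization": item.normalization,
            }
        )
    # %.17g preserves binary64 exactly so write/read round-trips bit-for-bit
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_measurements(path) -> list[MeasurementItem]:
    """Read a measurement table, validating the schema row by row.

    Raises :class:`SchemaError` naming the offending column or (1-based
    data) row on any violation.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    items: list[MeasurementItem] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            inputs = CellInputs(
                mg=float(row.mg_mM),
                tnf=float(row.tnf_ng_ml),
                il10=float(row.il10_ng_ml),
                il8=float(row.il8_ng_ml),
                il1b=float(row.il1b_ng_ml),
                il10_exposure=float(row.exposure_h),
            )
            item = MeasurementItem(
                study_id=int(row.study_id),
                marker=str(row.marker),
                day=float(row.day),
                condition=str(row.condition),
                value=float(row.value),
                sd=float(row.sd),
                inputs=inputs,
                normalization=str(row.normalization),
            )
        except Exception as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
        items.append(item)
    return items
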