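"""Core projection mathematics.

The model assumes that each complication's incidence falls by a constant
fraction ``a`` for every 1 percentage-point absolute reduction in HbA1c:

    I(h_target) = I(h_source) * (1 - a) ** (h_source - h_target)

The exponent is continuous, so fractional HbA1c differences (e.g. a 0.5%
reduction) are supported. Sign convention: the exponent is
``h_source - h_target``, so moving to a LOWER target HbA1c divides fewer
powers of (1-a) away — i.e. incidence falls when HbA1c falls. Getting this
sign wrong is the classic failure mode; the tests pin it.

Expected events over the horizon:
  * recurrent complications:  n * i * horizon (occurrences per patient-year);
  * once-only complications:  n * (1 - (1 - i) ** horizon) — the pool of
    complication-free patients depletes; at horizon 1 this equals n * i.

Complications are treated as independent (no competing risks, no
interaction); hospitalization and mortality are not modeled, which avoids
double counting their cost inside the included complications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ProjectionError
from .evidence_model import (
    SUPPORTED_HBA1C_WINDOW,
    IncidenceRecord,
    ParameterSet,
    PopulationModel,
)


class Population(BaseModel):
    """The studied population: size, baseline HbA1c and planned reduction.

    The model targets average insulin-treated diabetes populations with
    baseline HbA1c inside 6.5-11.5%; set ``allow_out_of_range`` to override
    deliberately (results outside the window are extrapolations).
    """

    model_config = ConfigDict(frozen=True)

    n: float = Field(gt=0.0)
    baseline_hba1c: float
    delta_hba1c: float = Field(default=0.0, ge=0.0,
                               description="absolute percentage-point HbA1c reduction")
    horizon_years: int = Field(default=1, ge=1)
    population_model: PopulationModel = "mixed"
    allow_out_of_range: bool = False
    hba1c_floor: float = SUPPORTED_HBA1C_WINDOW[0]

    @model_validator(mode="after")
    def _window(self) -> "Population":
        lo, hi = SUPPORTED_HBA1C_WINDOW
        if not self.allow_out_of_range:
            if not (lo <= self.baseline_hba1c <= hi):
                raise ValueError(
                    f"baseline HbA1c {self.baseline_hba1c}% outside the supported "
                    f"range {lo}%-{hi}% (set allow_out_of_range to override)")
            if self.baseline_hba1c - self.delta_hba1c < self.hba1c_floor:
                raise ValueError(
                    f"baseline {self.baseline_hba1c}% minus reduction {self.delta_hba1c}% "
                    f"falls below the supported floor {self.hba1c_floor}%")
        return self


@dataclass
class EventProjection:
    """Expected and prevented event counts per complication over the horizon."""

    expected: dict[str, float]
    prevented: dict[str, float] = field(default_factory=dict)
    horizon_years: int = 1

    def __post_init__(self) -> None:
        if not self.prevented:
            self.prevented = {cid: 0.0 for cid in self.expected}

    @property
    def total_expected(self) -> float:
        return float(sum(self.expected.values()))

    @property
    def total_prevented(self) -> float:
        return float(sum(self.prevented.values()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"expected_events": self.expected,
                           "prevented_events": self.prevented})
        df.index.name = "complication_id"
        return df


def transfer_incidence(i_source: float, a: float, h_source: float, h_target: float) -> float:
    """Transfer an incidence between HbA1c levels with the exponential model.

    Returns ``i_source * (1 - a) ** (h_source - h_target)``; composes exactly
    across intermediate levels and round-trips to machine precision.
    """
    if not (0.0 < a < 1.0):
        raise ProjectionError(f"effect size a={a} outside (0, 1)")
    if not (math.isfinite(i_source) and i_source >= 0.0):
        raise ProjectionError(f"incidence {i_source!r} must be finite and >= 0")
    return i_source * (1.0 - a) ** (h_source - h_target)


def normalize_incidence(record: IncidenceRecord, a: float, reference_hba1c: float) -> float:
    """Normalize a reported incidence to the reference HbA1c using ``a``."""
    if record.study_mean_hba1c is None:
        raise ProjectionError(
            f"incidence record '{record.source_id}' has no study mean HbA1c; "
            "cannot normalize")
    return transfer_incidence(record.incidence, a, record.study_mean_hba1c, reference_hba1c)


def _expected_one(cp, pop_n: float, baseline_hba1c: float, horizon: int,
                  reference_hba1c: float) -> float:
    i0 = transfer_incidence(cp.i_ref, cp.a, reference_hba1c, baseline_hba1c)
    if cp.spec.recurrence == "recurrent":
        return pop_n * i0 * horizon
    if i0 > 1.0:
        raise ProjectionError(
            f"once-only complication '{cp.spec.id}': incidence {i0:.4g} > 1 after "
            f"transfer to HbA1c {baseline_hba1c}% — outside model validity")
    return pop_n * (1.0 - (1.0 - i0) ** horizon)


def expected_events(pop: Population, params: ParameterSet,
                    baseline_hba1c: Optional[float] = None) -> EventProjection:
    """Expected events per complication at the population's baseline HbA1c."""
    h = pop.baseline_hba1c if baseline_hba1c is None else baseline_hba1c
    expected = {
        cid: _expected_one(cp, pop.n, h, pop.horizon_years, params.reference_hba1c)
        for cid, cp in params.complications.items()
    }
    return EventProjection(expected=expected, horizon_years=pop.horizon_years)


def prevented_events(pop: Population, params: ParameterSet) -> EventProjection:
    """Expected events at baseline and events prevented by the HbA1c reduction.

    Prevented counts are the difference between the projection at the
    baseline HbA1c and at baseline − delta. For recurrent complications the
    prevented fraction is exactly ``1 - (1 - a) ** delta`` of the expected
    count, independent of incidence and population size.
    """
    before = expected_events(pop, params)
    after = expected_events(pop, params, baseline_hba1c=pop.baseline_hba1c - pop.delta_hba1c)
    prevented = {cid: before.expected[cid] - after.expected[cid] for cid in before.expected}
    return EventProjection(expected=before.expected, prevented=prevented,
                           horizon_years=pop.horizon_years)
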