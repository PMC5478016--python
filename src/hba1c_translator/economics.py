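"""Attach costs to projected events: totals, savings and percentage summaries.

Cost of one event is the entry amount for ``per_event`` entries, or the
annual amount times the user-defined horizon N for ``ongoing_annual``
entries (e.g. dialysis). All money stays in the cost set's currency; no
conversion, inflation adjustment or discounting is applied.

Percentages are computed from unrounded totals and rounded half-up to one
decimal only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .errors import MissingComplicationError, ParameterError
from .evidence_model import CostDataSet, CostEntry
from .risk_engine import EventProjection


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent_of(part: float, whole: float) -> float:
    """Percentage of ``part`` in ``whole``, rounded half-up to 1 decimal.

    This is the single percentage path used by every report; zero whole
    yields 0.0 rather than a division error.
    """
    if whole == 0:
        return 0.0
    return round_half_up(100.0 * part / whole, 1)


def cost_per_event(entry: CostEntry) -> float:
    """Money attached to one event: amount, or annual amount over N years."""
    if entry.mode == "per_event":
        return entry.amount
    return entry.amount * entry.horizon_years


@dataclass
class CostProjection:
    """Money attached to an event projection, plus percentage summaries."""

    expected_cost: dict[str, float]
    cost_savings: dict[str, float]
    currency: str
    percent_prevented_events: float
    percent_cost_savings: float

    @property
    def total_expected_cost(self) -> float:
        return float(sum(self.expected_cost.values()))

    @property
    def total_cost_savings(self) -> float:
        return float(sum(self.cost_savings.values()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"expected_cost": self.expected_cost,
                           "cost_savings": self.cost_savings})
        df.index.name = "complication_id"
        return df


def project_costs(events: EventProjection, costs: CostDataSet,
                  expected_currency: Optional[str] = None) -> CostProjection:
    """Multiply events by per-event costs; summarize with 1-decimal percentages.

    ``percent_prevented_events`` is prevented/expected events;
    ``percent_cost_savings`` is savings/expected cost — both over totals.
    """
    if expected_currency is not None and costs.currency != expected_currency:
        raise ParameterError(
            f"cost data set currency {costs.currency} does not match expected "
            f"{expected_currency}; no conversion is performed")
    expected_cost: dict[str, float] = {}
    cost_savings: dict[str, float] = {}
    for cid, n_expected in events.expected.items():
        entry = costs.entries.get(cid)
        if entry is None:
            raise MissingComplicationError(cid, f"cost data set {costs.country}/{costs.source_id}")
        per_event = cost_per_event(entry)
        expected_cost[cid] = n_expected * per_event
        cost_savings[cid] = events.prevented[cid] * per_event
    return CostProjection(
        expected_cost=expected_cost,
        cost_savings=cost_savings,
        currency=costs.currency,
        percent_prevented_events=percent_of(events.total_prevented, events.total_expected),
        percent_cost_savings=percent_of(sum(cost_savings.values()), sum(expected_cost.values())),
    )
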