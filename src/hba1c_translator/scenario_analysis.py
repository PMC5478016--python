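"""Deterministic sensitivity and scenario analyses.

Three analyses probe the projection's robustness:

* one-way (tornado) sensitivity — every incidence, association and cost is
  varied by ±10% one at a time (multiplicative); baseline HbA1c by ±0.5
  percentage points absolute (±10% of the supported 6.5-11.5 window); and
  the population model is swapped across available parameter sets;
* best/worst-case range scenarios — all incidences and associations set
  simultaneously to their literature maxima (best case for an HbA1c
  reduction: more preventable events) or minima;
* a population-model comparison emitting per-patient totals for each
  parameter set (total incidence, prevented events per 1% HbA1c reduction,
  total cost, savings per 1% reduction).

Structural facts worth knowing: cost perturbations cannot move event
counts and act linearly on savings; incidence perturbations act linearly
on both; association and baseline-HbA1c perturbations act nonlinearly.
Perturbations that would violate a hard bound (an association pushed to
1 or beyond) are reported as failed rows, never silently clamped; the
baseline-HbA1c rows are the one stated exception, clamped to the
supported window with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .economics import CostProjection, project_costs
from .errors import ParameterError
from .evidence_model import (
    SUPPORTED_HBA1C_WINDOW,
    CostDataSet,
    CostEntry,
    ParameterSet,
)
from .risk_engine import EventProjection, Population, prevented_events

logger = logging.getLogger(__name__)

RELATIVE_STEP = 0.10          # ±10% multiplicative on incidences, associations, costs
BASELINE_HBA1C_STEP = 0.5     # ±0.5 percentage points absolute on baseline HbA1c


@dataclass(frozen=True)
class SensitivityOutcome:
    prevented_events_total: float
    cost_savings_total: float


@dataclass(frozen=True)
class SensitivityRow:
    """Result of varying one parameter down and up, all else at baseline."""

    parameter: str
    baseline_result: SensitivityOutcome
    low_result: Optional[SensitivityOutcome] = None
    high_result: Optional[SensitivityOutcome] = None
    error: Optional[str] = None

    @property
    def spread(self) -> float:
        if self.low_result is None or self.high_result is None:
            return float("nan")
        return abs(self.high_result.cost_savings_total - self.low_result.cost_savings_total)


def _outcome(pop: Population, params: ParameterSet, costs: CostDataSet) -> SensitivityOutcome:
    events = prevented_events(pop, params)
    money = project_costs(events, costs)
    return SensitivityOutcome(prevented_events_total=events.total_prevented,
                              cost_savings_total=money.total_cost_savings)


def _scaled_params(params: ParameterSet, cid: str, pillar: str, factor: float) -> ParameterSet:
    doc = params.model_copy(deep=True)
    cp = doc.complications[cid]
    if pillar == "incidence":
        new_cp = cp.model_copy(update={"i_ref": cp.i_ref * factor})
    else:  # association
        new_a = cp.a * factor
        if not (0.0 < new_a < 1.0):
            raise ParameterError(f"{cid}: association {cp.a:g} x {factor:g} = {new_a:g} "
                                 "leaves (0, 1)")
        new_cp = cp.model_copy(update={"a": new_a})
    doc.complications[cid] = new_cp
    return doc


def _scaled_costs(costs: CostDataSet, cid: str, factor: float) -> CostDataSet:
    entry = costs.entries[cid]
    new_entry = CostEntry(mode=entry.mode, amount=entry.amount * factor,
                          currency=entry.currency, price_year=entry.price_year,
                          horizon_years=entry.horizon_years)
    new_entries = dict(costs.entries)
    new_entries[cid] = new_entry
    return costs.model_copy(update={"entries": new_entries})


def one_way_sensitivity(
    pop: Population,
    params: ParameterSet,
    costs: CostDataSet,
    alt_params: Optional[Mapping[str, ParameterSet]] = None,
) -> list[SensitivityRow]:
    """One-at-a-time perturbation of every model input.

    Returns one row per parameter: each complication's incidence,
    association and cost at x0.9 / x1.1; baseline HbA1c at ∓0.5 absolute
    (clamped to the supported window with a warning); and, when
    ``alt_params`` provides them, the projection under alternative
    population models. A perturbation that violates a hard bound flags its
    row as failed; the remaining rows still run.
    """
    baseline = _outcome(pop, params, costs)
    lo_f, hi_f = 1.0 - RELATIVE_STEP, 1.0 + RELATIVE_STEP
    rows: list[SensitivityRow] = []

    for cid in params.complications:
        for pillar in ("incidence", "association"):
            try:
                low = _outcome(pop, _scaled_params(params, cid, pillar, lo_f), costs)
                high = _outcome(pop, _scaled_params(params, cid, pillar, hi_f), costs)
                rows.append(SensitivityRow(f"{cid}:{pillar}", baseline, low, high))
            except ParameterError as exc:
                rows.append(SensitivityRow(f"{cid}:{pillar}", baseline, error=str(exc)))
        low = _outcome(pop, params, _scaled_costs(costs, cid, lo_f))
        high = _outcome(pop, params, _scaled_costs(costs, cid, hi_f))
        rows.append(SensitivityRow(f"{cid}:cost", baseline, low, high))

    # baseline HbA1c +-0.5 absolute, clamped to the supported window
    lo_w, hi_w = SUPPORTED_HBA1C_WINDOW
    shifted: dict[str, SensitivityOutcome] = {}
    for label, shift in (("low", -BASELINE_HBA1C_STEP), ("high", BASELINE_HBA1C_STEP)):
        h = pop.baseline_hba1c + shift
        clamped = min(max(h, lo_w), hi_w)
        if clamped != h:
            logger.warning("baseline HbA1c %+0.1f gives %.2f%%, clamped to %.2f%%",
                           shift, h, clamped)
        shifted_pop = pop.model_copy(update={"baseline_hba1c": clamped,
                                             "allow_out_of_range": True})
        shifted[label] = _outcome(shifted_pop, params, costs)
    rows.append(SensitivityRow("baseline_hba1c", baseline, shifted["low"], shifted["high"]))

    for name, alt in (alt_params or {}).items():
        alt_outcome = _outcome(pop, alt, costs)
        rows.append(SensitivityRow(f"population_model:{name}", baseline,
                                   alt_outcome, alt_outcome))
    return rows


def tornado_table(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    """Tornado layout: rows sorted by cost-savings spread, widest first."""
    records = []
    for row in rows:
        records.append({
            "parameter": row.parameter,
            "prevented_low": row.low_result.prevented_events_total if row.low_result else None,
            "prevented_high": row.high_result.prevented_events_total if row.high_result else None,
            "prevented_baseline": row.baseline_result.prevented_events_total,
            "savings_low": row.low_result.cost_savings_total if row.low_result else None,
            "savings_high": row.high_result.cost_savings_total if row.high_result else None,
            "savings_baseline": row.baseline_result.cost_savings_total,
            "spread": row.spread,
            "error": row.error or "",
        })
    df = pd.DataFrame.from_records(records)
    return df.sort_values("spread", ascending=False, na_position="last").reset_index(drop=True)


def tornado_plot(rows: Sequence[SensitivityRow], path: str) -> None:
    """Write a horizontal-bar tornado diagram of cost-savings spreads."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tornado_table(rows).dropna(subset=["savings_low"])[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
    base = df["savings_baseline"]
    ax.barh(df["parameter"], df["savings_high"] - base, left=base, color="#d95f02", label="+10% / high")
    ax.barh(df["parameter"], df["savings_low"] - base, left=base, color="#1b9e77", label="-10% / low")
    ax.axvline(base.iloc[0], color="k", lw=0.8)
    ax.set_xlabel("total cost savings")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Best / worst case range scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeScenario:
    """Projection with every incidence and association at a range extreme."""

    mode: str  # "min_all" or "max_all"
    events: EventProjection
    money: CostProjection

    @property
    def results(self) -> dict[str, float]:
        return {
            "expected_events": self.events.total_expected,
            "prevented_events": self.events.total_prevented,
            "expected_cost": self.money.total_expected_cost,
            "cost_savings": self.money.total_cost_savings,
            "percent_prevented_events": self.money.percent_prevented_events,
            "percent_cost_savings": self.money.percent_cost_savings,
        }


def _extreme_params(params: ParameterSet, which: str) -> ParameterSet:
    doc = params.model_copy(deep=True)
    for cid, cp in params.complications.items():
        updates = {}
        for pillar, attr in (("effect_size", "a"), ("incidence", "i_ref")):
            rng = cp.ranges.get(pillar)
            if rng is None:
                raise ParameterError(
                    f"complication '{cid}' has no {pillar} literature range; "
                    "range scenarios need one per complication")
            updates[attr] = rng.low if which == "min_all" else rng.high
        doc.complications[cid] = cp.model_copy(update=updates)
    return doc


def range_scenarios(pop: Population, params: ParameterSet,
                    costs: CostDataSet) -> tuple[RangeScenario, RangeScenario]:
    """Worst-case (all literature minima) and best-case (all maxima) projections.

    Costs stay at the selected cost data set; only incidences and
    associations move to their documented range extremes.
    """
    scenarios = []
    for mode in ("min_all", "max_all"):
        extreme = _extreme_params(params, mode)
        events = prevented_events(pop, extreme)
        scenarios.append(RangeScenario(mode=mode, events=events,
                                       money=project_costs(events, costs)))
    return scenarios[0], scenarios[1]


# ---------------------------------------------------------------------------
# Population-model comparison (per-patient totals per parameter set)
# ---------------------------------------------------------------------------

COMPARISON_ROWS = (
    "total_incidence",
    "prevented_events_per_1pct_hba1c",
    "total_cost",
    "cost_savings_per_1pct_hba1c",
)


def compare_population_models(
    pop: Population,
    sets: Mapping[str, ParameterSet],
    costs: CostDataSet,
) -> pd.DataFrame:
    """Per-patient totals for each population model's parameter set.

    Rows: total incidence (expected events per patient-year at the
    population baseline), prevented events per 1% HbA1c reduction, total
    cost per patient, and cost savings per 1% reduction. Columns: one per
    parameter set. Pass the raw-incidence and normalized-incidence groups
    separately to compare both.
    """
    if not sets:
        raise ParameterError("no parameter sets to compare")
    per_patient = pop.model_copy(update={"n": 1.0, "delta_hba1c": 1.0, "horizon_years": 1,
                                         "allow_out_of_range": True})
    columns: dict[str, list[float]] = {}
    for name, params in sets.items():
        events = prevented_events(per_patient, params)
        money = project_costs(events, costs)
        columns[name] = [events.total_expected, events.total_prevented,
                         money.total_expected_cost, money.total_cost_savings]
    df = pd.DataFrame(columns, index=list(COMPARISON_ROWS))
    df.index.name = "outcome"
    return df
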