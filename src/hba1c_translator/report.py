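"""Report writer: per-complication tables plus totals, as text and JSON.

The human-readable table and the machine-readable JSON are generated from
the same projection objects; the percentage fields in both come from the
single rounding path in :func:`hba1c_translator.economics.percent_of`, so
a report's percentages always equal the hand-recomputed ratios of its own
absolute fields after 1-decimal rounding.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .economics import CostProjection
from .evidence_model import ParameterSet
from .risk_engine import EventProjection, Population


def report_frame(events: EventProjection, money: CostProjection,
                 params: Optional[ParameterSet] = None) -> pd.DataFrame:
    """Per-complication table with a TOTAL row."""
    df = events.to_frame().join(money.to_frame())
    if params is not None:
        df.insert(0, "complication",
                  [params.complications[cid].spec.display_name for cid in df.index])
    total = df.sum(numeric_only=True)
    total.name = "TOTAL"
    if params is not None:
        total["complication"] = "TOTAL"
    return pd.concat([df, total.to_frame().T])


def report_dict(pop: Population, events: EventProjection, money: CostProjection,
                extra: Optional[Mapping] = None) -> dict:
    doc = {
        "population": {
            "n": pop.n,
            "baseline_hba1c": pop.baseline_hba1c,
            "delta_hba1c": pop.delta_hba1c,
            "horizon_years": pop.horizon_years,
            "population_model": pop.population_model,
        },
        "currency": money.currency,
        "per_complication": {
            cid: {
                "expected_events": events.expected[cid],
                "prevented_events": events.prevented[cid],
                "expected_cost": money.expected_cost[cid],
                "cost_savings": money.cost_savings[cid],
            }
            for cid in events.expected
        },
        "totals": {
            "expected_events": events.total_expected,
            "prevented_events": events.total_prevented,
            "expected_cost": money.total_expected_cost,
            "cost_savings": money.total_cost_savings,
            "percent_prevented_events": money.percent_prevented_events,
            "percent_cost_savings": money.percent_cost_savings,
        },
    }
    if extra:
        doc.update(extra)
    return doc


def write_projection_report(outdir: str | Path, pop: Population,
                            events: EventProjection, money: CostProjection,
                            params: Optional[ParameterSet] = None,
                            stem: str = "report") -> dict[str, Path]:
    """Write ``<stem>.json`` and ``<stem>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"json": outdir / f"{stem}.json", "csv": outdir / f"{stem}.csv"}
    paths["json"].write_text(json.dumps(report_dict(pop, events, money), indent=2))
    report_frame(events, money, params).to_csv(paths["csv"], index_label="complication_id")
    return paths


def summary_lines(pop: Population, events: EventProjection,
                  money: CostProjection) -> list[str]:
    """The Discussion-style one-paragraph summary of a projection."""
    cur = money.currency
    return [
        f"Population: n={pop.n:g}, baseline HbA1c {pop.baseline_hba1c:g}%, "
        f"reduction {pop.delta_hba1c:g}%, horizon {pop.horizon_years} y "
        f"({pop.population_model} model)",
        f"Expected events: {events.total_expected:.2f}   "
        f"expected cost: {money.total_expected_cost:,.0f} {cur}",
        f"Prevented events: {events.total_prevented:.2f} "
        f"[{money.percent_prevented_events:.1f}%]   "
        f"cost savings: {money.total_cost_savings:,.0f} {cur} "
        f"[{money.percent_cost_savings:.1f}%]",
    ]
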