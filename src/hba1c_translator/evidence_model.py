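"""Domain types for the three evidence pillars and their file formats.

The model rests on three pillars per complication: an association (effect
size) of incidence with HbA1c, a baseline incidence normalized to a common
reference HbA1c, and an average cost per event. This module defines those
types, the literature ranges used to warn about implausible user input
(e.g. a prevalence typed where an incidence belongs), and the registry of
country cost data sets.

Hard type invariants (an effect size outside (0, 1), a negative cost) are
errors; values outside a documented literature range only produce warnings,
collected structurally and logged at WARN level.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import (
    AmbiguousCostSetError,
    MissingComplicationError,
    ParameterError,
    UnknownCountryError,
)

logger = logging.getLogger(__name__)

Category = Literal["cardiovascular", "brain", "eye", "peripheral", "renal"]
Recurrence = Literal["once_only", "recurrent"]
DiabetesType = Literal["t1", "t2", "mixed"]
PopulationModel = Literal["t1", "t2", "total_average", "mixed"]
Pillar = Literal["effect_size", "incidence", "cost"]
CostMode = Literal["per_event", "ongoing_annual"]

#: Default reference HbA1c (%) to which incidences are normalized — the
#: average baseline HbA1c across the incidence evidence base.
REFERENCE_HBA1C = 8.56

#: Supported baseline HbA1c window (%) for average insulin-treated populations.
SUPPORTED_HBA1C_WINDOW = (6.5, 11.5)

# Recurrence semantics fixed by the model definition: ESRD and blindness
# happen at most once per patient; MI and DKA are counted per occurrence.
_FIXED_RECURRENCE: dict[str, Recurrence] = {
    "esrd": "once_only",
    "blindness": "once_only",
    "mi": "recurrent",
    "dka": "recurrent",
}


class ComplicationSpec(BaseModel):
    """Identity and recurrence semantics of one modeled complication.

    ``once_only`` complications (e.g. ESRD, blindness) count new cases per
    year among patients who never had the complication; ``recurrent`` ones
    (e.g. MI, DKA) count total occurrences per patient-year.
    """

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    display_name: str
    category: Category
    recurrence: Recurrence

    @model_validator(mode="after")
    def _check_fixed_recurrence(self) -> "ComplicationSpec":
        fixed = _FIXED_RECURRENCE.get(self.id)
        if fixed is not None and self.recurrence != fixed:
            raise ValueError(f"complication '{self.id}' must be {fixed}")
        return self


class EffectSize(BaseModel):
    """One study's relative incidence reduction per 1% absolute HbA1c decrease.

    ``a`` is the constant fraction by which the incidence drops for every
    1 percentage-point HbA1c reduction; person-years carry the pooling weight.
    """

    model_config = ConfigDict(frozen=True)

    a: float = Field(gt=0.0, lt=1.0,
                     description="fractional incidence reduction per 1% absolute HbA1c decrease")
    person_years: float = Field(gt=0.0)
    study_mean_hba1c: Optional[float] = None
    diabetes_type: DiabetesType = "mixed"
    source_id: str = ""


class IncidenceRecord(BaseModel):
    """A reported incidence together with the study's mean HbA1c."""

    model_config = ConfigDict(frozen=True)

    incidence: float = Field(ge=0.0)
    study_mean_hba1c: Optional[float] = Field(default=None, gt=4.0, lt=20.0)
    diabetes_type: DiabetesType = "mixed"
    person_years: float = Field(gt=0.0)
    source_id: str = ""


class CostEntry(BaseModel):
    """Cost of one complication: per event, or annual ongoing over N years.

    For ``ongoing_annual`` entries the model charges ``amount`` per year over
    ``horizon_years`` (e.g. dialysis); ``per_event`` entries already include
    any follow-up cost over the horizon.
    """

    model_config = ConfigDict(frozen=True)

    mode: CostMode
    amount: float = Field(ge=0.0)
    currency: str = Field(min_length=3, max_length=3)
    price_year: int = Field(ge=1980, le=2100)
    horizon_years: int = Field(default=1, ge=1)


class LiteratureRange(BaseModel):
    """Documented low/high of previously reported values for one pillar."""

    model_config = ConfigDict(frozen=True)

    pillar: Pillar
    complication_id: str
    low: float
    high: float
    diabetes_type: DiabetesType = "mixed"

    @model_validator(mode="after")
    def _ordered(self) -> "LiteratureRange":
        if self.low > self.high:
            raise ValueError(f"range low {self.low} > high {self.high}")
        return self


class CostDataSet(BaseModel):
    """A country's complete complication cost table from one source."""

    country: str
    source_id: str
    currency: str = Field(min_length=3, max_length=3)
    price_year: int
    entries: dict[str, CostEntry]

    @model_validator(mode="after")
    def _uniform_currency(self) -> "CostDataSet":
        for cid, entry in self.entries.items():
            if entry.currency != self.currency:
                raise ValueError(
                    f"entry '{cid}' currency {entry.currency} differs from data set {self.currency}"
                )
        return self

    def require_complete(self, complication_ids: Iterable[str]) -> None:
        for cid in complication_ids:
            if cid not in self.entries:
                raise MissingComplicationError(
                    cid, f"cost data set {self.country}/{self.source_id}")


class ComplicationParameters(BaseModel):
    """Assembled per-complication parameters: one value per pillar plus ranges."""

    spec: ComplicationSpec
    a: float = Field(gt=0.0, lt=1.0)
    i_ref: float = Field(ge=0.0, description="incidence normalized to the reference HbA1c")
    cost: CostEntry
    ranges: dict[Pillar, LiteratureRange] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _once_only_bound(self) -> "ComplicationParameters":
        if self.spec.recurrence == "once_only" and self.i_ref > 1.0:
            raise ValueError(
                f"once-only complication '{self.spec.id}' has incidence {self.i_ref} > 1")
        return self


class ParameterSet(BaseModel):
    """Everything needed to project one population: all complications' parameters."""

    complications: dict[str, ComplicationParameters]
    reference_hba1c: float = REFERENCE_HBA1C
    population_model: PopulationModel = "mixed"

    @model_validator(mode="after")
    def _ids_consistent(self) -> "ParameterSet":
        lo, hi = SUPPORTED_HBA1C_WINDOW
        if not (lo <= self.reference_hba1c <= hi):
            raise ValueError(
                f"reference_hba1c {self.reference_hba1c} outside supported window {lo}-{hi}")
        for key, cp in self.complications.items():
            if key != cp.spec.id:
                raise ValueError(f"key '{key}' does not match spec id '{cp.spec.id}'")
        return self

    @property
    def complication_ids(self) -> list[str]:
        return list(self.complications)


#: The ten modeled complications. Recurrence for ESRD, blindness, MI and DKA
#: is fixed by the model definition; the rest is configuration (replaceable).
DEFAULT_COMPLICATIONS: tuple[ComplicationSpec, ...] = (
    ComplicationSpec(id="angina", display_name="Angina pectoris",
                     category="cardiovascular", recurrence="recurrent"),
    ComplicationSpec(id="chf", display_name="Coronary heart failure",
                     category="cardiovascular", recurrence="once_only"),
    ComplicationSpec(id="mi", display_name="Myocardial infarction",
                     category="cardiovascular", recurrence="recurrent"),
    ComplicationSpec(id="stroke", display_name="Stroke",
                     category="brain", recurrence="recurrent"),
    ComplicationSpec(id="dka", display_name="Diabetic ketoacidosis",
                     category="brain", recurrence="recurrent"),
    ComplicationSpec(id="pr", display_name="Proliferative retinopathy",
                     category="eye", recurrence="once_only"),
    ComplicationSpec(id="blindness", display_name="Severe vision loss",
                     category="eye", recurrence="once_only"),
    ComplicationSpec(id="amputation", display_name="Amputation",
                     category="peripheral", recurrence="recurrent"),
    ComplicationSpec(id="neuropathy", display_name="Neuropathy",
                     category="peripheral", recurrence="once_only"),
    ComplicationSpec(id="esrd", display_name="End-stage renal disease",
                     category="renal", recurrence="once_only"),
)

DEFAULT_COMPLICATION_IDS: tuple[str, ...] = tuple(c.id for c in DEFAULT_COMPLICATIONS)

_SPEC_BY_ID: dict[str, ComplicationSpec] = {c.id: c for c in DEFAULT_COMPLICATIONS}


ValidationOutcome = Literal["ok", "warn_low", "warn_high"]


@dataclass(frozen=True)
class RangeWarning:
    """A structurally collected out-of-range warning (never fatal)."""

    complication_id: str
    pillar: Pillar
    value: float
    outcome: ValidationOutcome
    low: float
    high: float

    def __str__(self) -> str:
        rel = "below" if self.outcome == "warn_low" else "above"
        return (f"{self.complication_id}/{self.pillar}: value {self.value:g} is {rel} the "
                f"documented literature range [{self.low:g}, {self.high:g}]")


def validate_value(value: float, range_: LiteratureRange) -> ValidationOutcome:
    """Compare a user value against the documented literature range.

    Returns ``ok`` iff ``low <= value <= high`` (boundaries inclusive);
    otherwise ``warn_low`` / ``warn_high``. This is the guard against
    extreme figures such as a prevalence typed where an incidence belongs.
    """
    if not math.isfinite(value):
        raise ParameterError(f"non-finite value {value!r} for {range_.complication_id}/{range_.pillar}")
    if value < range_.low:
        return "warn_low"
    if value > range_.high:
        return "warn_high"
    return "ok"


def collect_warnings(params: ParameterSet) -> list[RangeWarning]:
    """Run every parameter against its literature range; return all warnings."""
    warnings: list[RangeWarning] = []
    for cid, cp in params.complications.items():
        checks: list[tuple[Pillar, float]] = [("effect_size", cp.a), ("incidence", cp.i_ref),
                                              ("cost", cp.cost.amount)]
        for pillar, value in checks:
            rng = cp.ranges.get(pillar)
            if rng is None:
                continue
            outcome = validate_value(value, rng)
            if outcome != "ok":
                w = RangeWarning(cid, pillar, value, outcome, rng.low, rng.high)
                logger.warning("%s", w)
                warnings.append(w)
    return warnings


# ---------------------------------------------------------------------------
# Parameter set I/O (JSON document; delimited table for spreadsheet interop)
# ---------------------------------------------------------------------------

def parameter_set_to_dict(params: ParameterSet) -> dict:
    doc: dict = {
        "reference_hba1c": params.reference_hba1c,
        "population_model": params.population_model,
        "complications": [],
    }
    for cp in params.complications.values():
        entry = {
            "id": cp.spec.id,
            "display_name": cp.spec.display_name,
            "category": cp.spec.category,
            "recurrence": cp.spec.recurrence,
            "effect_size": cp.a,
            "incidence": cp.i_ref,
            "cost": cp.cost.model_dump(),
            "ranges": {p: [r.low, r.high] for p, r in cp.ranges.items()},
        }
        doc["complications"].append(entry)
    return doc


def parameter_set_from_dict(doc: Mapping) -> ParameterSet:
    complications: dict[str, ComplicationParameters] = {}
    for row in doc.get("complications", []):
        cid = str(row.get("id", "?"))
        try:
            spec = ComplicationSpec(
                id=cid,
                display_name=row.get("display_name", cid),
                category=row["category"],
                recurrence=row["recurrence"],
            )
            ranges = {
                pillar: LiteratureRange(pillar=pillar, complication_id=cid,
                                        low=float(lohi[0]), high=float(lohi[1]))
                for pillar, lohi in (row.get("ranges") or {}).items()
            }
            complications[cid] = ComplicationParameters(
                spec=spec,
                a=row["effect_size"],
                i_ref=row["incidence"],
                cost=CostEntry(**row["cost"]),
                ranges=ranges,
            )
        except (ValidationError, KeyError, TypeError, ValueError) as exc:
            raise ParameterError(f"complication '{cid}': {exc}") from exc
    try:
        return ParameterSet(
            complications=complications,
            reference_hba1c=doc.get("reference_hba1c", REFERENCE_HBA1C),
            population_model=doc.get("population_model", "mixed"),
        )
    except ValidationError as exc:
        raise ParameterError(str(exc)) from exc


def write_parameter_set(params: ParameterSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(parameter_set_to_dict(params), indent=2))
    return path


def _load_table(path: Path, currency: str, price_year: int) -> dict:
    """Read the one-row-per-complication delimited table into the JSON layout.

    Columns: complication_id, effect_size, incidence, study_hba1c,
    cost_amount, cost_mode, horizon_years. An ``incidence`` given with a
    ``study_hba1c`` is normalized to the reference on load.
    """
    from .risk_engine import transfer_incidence  # local import: avoids cycle

    df = pd.read_csv(path)
    required = {"complication_id", "effect_size", "incidence", "cost_amount", "cost_mode"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParameterError(f"table missing columns: {sorted(missing_cols)}")
    rows = []
    for idx, row in df.iterrows():
        cid = str(row["complication_id"])
        spec = _SPEC_BY_ID.get(cid)
        if spec is None:
            raise ParameterError(f"row {idx}: unknown complication_id '{cid}'")
        try:
            a = float(row["effect_size"])
            incidence = float(row["incidence"])
            study_h = row.get("study_hba1c")
            if study_h is not None and not pd.isna(study_h):
                incidence = transfer_incidence(incidence, a, float(study_h), REFERENCE_HBA1C)
            horizon = int(row["horizon_years"]) if "horizon_years" in df.columns else 1
            cost = {
                "mode": str(row["cost_mode"]),
                "amount": float(row["cost_amount"]),
                "currency": currency,
                "price_year": price_year,
                "horizon_years": horizon,
            }
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"row {idx} ({cid}): malformed field: {exc}") from exc
        rows.append({
            "id": cid,
            "display_name": spec.display_name,
            "category": spec.category,
            "recurrence": spec.recurrence,
            "effect_size": a,
            "incidence": incidence,
            "cost": cost,
        })
    return {"complications": rows}


def load_parameter_set(
    path: str | Path,
    format: Optional[Literal["json", "table"]] = None,
    required_ids: Optional[Sequence[str]] = DEFAULT_COMPLICATION_IDS,
    currency: str = "EUR",
    price_year: int = 2013,
) -> tuple[ParameterSet, list[RangeWarning]]:
    """Load and validate a parameter set; return it with collected warnings.

    Out-of-range values against documented literature ranges warn (logged,
    returned); hard invariant violations and missing complications raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "table"
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParameterError(f"{path}: invalid JSON: {exc}") from exc
    else:
        doc = _load_table(path, currency=currency, price_year=price_year)
    params = parameter_set_from_dict(doc)
    if required_ids:
        for cid in required_ids:
            if cid not in params.complications:
                raise MissingComplicationError(cid, str(path))
    return params, collect_warnings(params)


# ---------------------------------------------------------------------------
# Cost data set registry
# ---------------------------------------------------------------------------

def write_cost_dataset(costs: CostDataSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(costs.model_dump(), indent=2))
    return path


def load_cost_dataset(path: str | Path) -> CostDataSet:
    path = Path(path)
    try:
        return CostDataSet(**json.loads(path.read_text()))
    except json.JSONDecodeError as exc:
        raise ParameterError(f"{path}: invalid JSON: {exc}") from exc
    except ValidationError as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def load_cost_registry(directory: str | Path) -> list[CostDataSet]:
    """Load every ``*.json`` cost data set under a directory."""
    directory = Path(directory)
    sets = [load_cost_dataset(p) for p in sorted(directory.glob("*.json"))]
    if not sets:
        raise ParameterError(f"no cost data sets found under {directory}")
    return sets


def get_cost_dataset(
    registry: Sequence[CostDataSet],
    country: str,
    source_id: Optional[str] = None,
) -> CostDataSet:
    """Select a country's cost data set, never guessing among several sources.

    Countries with several published sets (e.g. Canada, Sweden, UK, US)
    require an explicit ``source_id``; the error lists the candidates.
    """
    if not registry:
        raise ParameterError("empty cost data set registry")
    matches = [cs for cs in registry if cs.country.casefold() == country.casefold()]
    if not matches:
        raise UnknownCountryError(country, sorted({cs.country for cs in registry}))
    if source_id is not None:
        for cs in matches:
            if cs.source_id == source_id:
                return cs
        raise UnknownCountryError(f"{country}/{source_id}",
                                  sorted(cs.source_id for cs in matches))
    if len(matches) > 1:
        raise AmbiguousCostSetError(country, [cs.source_id for cs in matches])
    return matches[0]


def costs_from_parameter_set(params: ParameterSet, country: str = "(embedded)",
                             source_id: str = "parameter-set") -> CostDataSet:
    """View the parameter set's own cost entries as a cost data set."""
    entries = {cid: cp.cost for cid, cp in params.complications.items()}
    currencies = {e.currency for e in entries.values()}
    if len(currencies) != 1:
        raise ParameterError(f"parameter set mixes currencies: {sorted(currencies)}")
    price_years = [e.price_year for e in entries.values()]
    return CostDataSet(country=country, source_id=source_id,
                       currency=currencies.pop(), price_year=max(price_years),
                       entries=entries)
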