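"""Synthetic literature-like evidence generator.

The real evidence base behind the model (study-level effect sizes,
incidences at varying study HbA1c, country cost tables) is not shipped
here; this module generates a statistically similar stand-in so that the
whole pipeline — harmonization, pooling, projection, sensitivity — can be
exercised and its parameter recovery verified against known ground truth.

What it emulates: per complication, effect-size studies scattered around a
true association (additive Gaussian noise, person-year weights spanning
two orders of magnitude, study HbA1c in the 6.5-11.8% window reported for
association studies), and incidence studies that are noisy realizations of
the exponential risk model at their sampled study HbA1c (multiplicative
log-normal noise, study HbA1c in the wider 6.4-13.5% incidence window).
Literature ranges are the min/max over the generated studies and the
ground truth, so they always bracket it. Cost data sets are synthetic:
plausible magnitudes and structure (per-event vs ongoing-annual entries),
not published figures.

All randomness flows from the single seed in :class:`FixtureConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import ParameterError
from .evidence_model import (
    DEFAULT_COMPLICATIONS,
    REFERENCE_HBA1C,
    ComplicationParameters,
    ComplicationSpec,
    CostDataSet,
    CostEntry,
    CostMode,
    EffectSize,
    IncidenceRecord,
    LiteratureRange,
    ParameterSet,
    write_cost_dataset,
    write_parameter_set,
)
from .harmonization import pool_associations, pool_incidences
from .risk_engine import transfer_incidence


class ComplicationTruth(BaseModel):
    """Ground-truth parameters one complication's synthetic evidence is drawn from."""

    model_config = ConfigDict(frozen=True)

    spec: ComplicationSpec
    true_a: float = Field(gt=0.0, lt=1.0)
    true_i_ref: float = Field(gt=0.0)
    cost_amount: float = Field(ge=0.0)
    cost_mode: CostMode = "per_event"
    horizon_years: int = 1


def _truth(cid: str, a: float, i_ref: float, cost: float,
           mode: CostMode = "per_event", horizon: int = 1) -> ComplicationTruth:
    spec = next(c for c in DEFAULT_COMPLICATIONS if c.id == cid)
    return ComplicationTruth(spec=spec, true_a=a, true_i_ref=i_ref,
                             cost_amount=cost, cost_mode=mode, horizon_years=horizon)


#: Plausible synthetic ground truth for the ten complications: associations
#: around 0.12-0.35 per 1% HbA1c (microvascular stronger than macrovascular),
#: incidences per patient-year at the 8.56% reference, and order-of-magnitude
#: realistic EUR costs. Synthetic values, not published figures.
DEFAULT_TRUTH: tuple[ComplicationTruth, ...] = (
    _truth("angina", 0.14, 0.012, 3500.0),
    _truth("chf", 0.16, 0.010, 4200.0, "ongoing_annual", 3),
    _truth("mi", 0.14, 0.010, 22000.0),
    _truth("stroke", 0.12, 0.008, 30000.0),
    _truth("dka", 0.20, 0.030, 8000.0),
    _truth("pr", 0.30, 0.015, 6000.0),
    _truth("blindness", 0.25, 0.0025, 2800.0, "ongoing_annual", 5),
    _truth("amputation", 0.35, 0.004, 35000.0),
    _truth("neuropathy", 0.25, 0.030, 1200.0, "ongoing_annual", 5),
    _truth("esrd", 0.30, 0.002, 45000.0, "ongoing_annual", 5),
)


class FixtureConfig(BaseModel):
    """Study conditions for the synthetic evidence base.

    Defaults: 12 studies per pillar and complication; additive Gaussian
    noise (sd 0.02) on effect sizes; multiplicative log-normal noise
    (sigma 0.10) on incidences; study HbA1c sampled uniformly inside the
    windows observed in the respective literatures (effect-size studies
    6.5-11.8%, incidence studies 6.4-13.5%).
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    complications: tuple[ComplicationTruth, ...] = DEFAULT_TRUTH
    n_effect_studies: int = Field(default=12, ge=1)
    n_incidence_studies: int = Field(default=12, ge=1)
    effect_noise_sd: float = Field(default=0.02, ge=0.0)
    incidence_noise_sigma: float = Field(default=0.10, ge=0.0)
    effect_hba1c_window: tuple[float, float] = (6.5, 11.8)
    incidence_hba1c_window: tuple[float, float] = (6.4, 13.5)
    reference_hba1c: float = REFERENCE_HBA1C
    currency: str = "EUR"
    price_year: int = 2013


@dataclass
class GeneratedEvidence:
    """Everything the generator produced, with its ground truth attached."""

    config: FixtureConfig
    truth: ParameterSet
    effect_studies: dict[str, list[EffectSize]]
    incidence_records: dict[str, list[IncidenceRecord]]
    cost_sets: list[CostDataSet]
    ranges: dict[str, dict[str, LiteratureRange]]


def _truth_parameter_set(config: FixtureConfig,
                         ranges: dict[str, dict[str, LiteratureRange]]) -> ParameterSet:
    complications = {}
    for ct in config.complications:
        cost = CostEntry(mode=ct.cost_mode, amount=ct.cost_amount,
                         currency=config.currency, price_year=config.price_year,
                         horizon_years=ct.horizon_years)
        complications[ct.spec.id] = ComplicationParameters(
            spec=ct.spec, a=ct.true_a, i_ref=ct.true_i_ref, cost=cost,
            ranges=ranges.get(ct.spec.id, {}))
    return ParameterSet(complications=complications,
                        reference_hba1c=config.reference_hba1c)


def generate_evidence(config: FixtureConfig) -> GeneratedEvidence:
    """Draw the full synthetic evidence base; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    ref = config.reference_hba1c

    effect_studies: dict[str, list[EffectSize]] = {}
    incidence_records: dict[str, list[IncidenceRecord]] = {}
    ranges: dict[str, dict[str, LiteratureRange]] = {}

    for ct in config.complications:
        cid = ct.spec.id

        # effect-size studies: additive noise on a, log-uniform person-years
        lo, hi = config.effect_hba1c_window
        studies = []
        for k in range(config.n_effect_studies):
            a_k = float(np.clip(ct.true_a + rng.normal(0.0, config.effect_noise_sd),
                                1e-4, 1.0 - 1e-4))
            py = float(np.exp(rng.uniform(np.log(500.0), np.log(200000.0))))
            h = float(rng.uniform(lo, hi))
            studies.append(EffectSize(a=a_k, person_years=py, study_mean_hba1c=h,
                                      diabetes_type="mixed", source_id=f"{cid}-assoc-{k}"))
        effect_studies[cid] = studies

        # incidence studies: model realizations at sampled study HbA1c
        lo_i, hi_i = config.incidence_hba1c_window
        records = []
        for k in range(config.n_incidence_studies):
            h = float(rng.uniform(lo_i, hi_i))
            noise = float(np.exp(rng.normal(0.0, config.incidence_noise_sigma)))
            inc = transfer_incidence(ct.true_i_ref, ct.true_a, ref, h) * noise
            if ct.spec.recurrence == "once_only":
                inc = min(inc, 1.0)
            py = float(np.exp(rng.uniform(np.log(1000.0), np.log(500000.0))))
            records.append(IncidenceRecord(incidence=inc, study_mean_hba1c=h,
                                           diabetes_type="mixed", person_years=py,
                                           source_id=f"{cid}-inc-{k}"))
        incidence_records[cid] = records

        # documented ranges: min/max over studies and truth (always bracket truth);
        # incidences are compared on the normalized (reference HbA1c) scale
        a_values = [s.a for s in studies] + [ct.true_a]
        i_values = [transfer_incidence(r.incidence, ct.true_a, r.study_mean_hba1c, ref)
                    for r in records] + [ct.true_i_ref]
        cost_values = [ct.cost_amount * 0.7, ct.cost_amount * 1.3]
        ranges[cid] = {
            "effect_size": LiteratureRange(pillar="effect_size", complication_id=cid,
                                           low=min(a_values), high=max(a_values)),
            "incidence": LiteratureRange(pillar="incidence", complication_id=cid,
                                         low=min(i_values), high=max(i_values)),
            "cost": LiteratureRange(pillar="cost", complication_id=cid,
                                    low=min(cost_values), high=max(cost_values)),
        }

    # cost data sets: one Germany-like set at truth, three US-like noisy sets
    # (several sources for one country, to exercise explicit source selection)
    def cost_set(country: str, source: str, currency: str, scale: float,
                 noisy: bool) -> CostDataSet:
        entries = {}
        for ct in config.complications:
            factor = scale * (float(np.exp(rng.normal(0.0, 0.08))) if noisy else 1.0)
            entries[ct.spec.id] = CostEntry(mode=ct.cost_mode,
                                            amount=round(ct.cost_amount * factor, 2),
                                            currency=currency,
                                            price_year=config.price_year,
                                            horizon_years=ct.horizon_years)
        return CostDataSet(country=country, source_id=source, currency=currency,
                           price_year=config.price_year, entries=entries)

    cost_sets = [
        cost_set("Germany", "synthetic-de", config.currency, 1.0, noisy=False),
        cost_set("United States", "synthetic-us-a", "USD", 1.3, noisy=True),
        cost_set("United States", "synthetic-us-b", "USD", 1.4, noisy=True),
        cost_set("United States", "synthetic-us-c", "USD", 1.5, noisy=True),
    ]

    truth = _truth_parameter_set(config, ranges)
    return GeneratedEvidence(config=config, truth=truth,
                             effect_studies=effect_studies,
                             incidence_records=incidence_records,
                             cost_sets=cost_sets, ranges=ranges)


def pooled_parameter_set(evidence: GeneratedEvidence,
                         use: str = "weighted_mean") -> ParameterSet:
    """Recover a ParameterSet from the generated evidence via the pooling path.

    ``use`` selects the pooled association convention: the person-year
    ``weighted_mean`` or the representative ``selected`` study.
    """
    if use not in ("weighted_mean", "selected"):
        raise ParameterError(f"unknown pooling convention '{use}'")
    config = evidence.config
    complications = {}
    for ct in config.complications:
        cid = ct.spec.id
        pooled = pool_associations(evidence.effect_studies[cid])
        a = getattr(pooled, use)
        i_ref = pool_incidences(evidence.incidence_records[cid], a,
                                config.reference_hba1c)
        cost = CostEntry(mode=ct.cost_mode, amount=ct.cost_amount,
                         currency=config.currency, price_year=config.price_year,
                         horizon_years=ct.horizon_years)
        complications[cid] = ComplicationParameters(
            spec=ct.spec, a=a, i_ref=min(i_ref, 1.0) if ct.spec.recurrence == "once_only" else i_ref,
            cost=cost, ranges=evidence.ranges[cid])
    return ParameterSet(complications=complications,
                        reference_hba1c=config.reference_hba1c)


def raw_mean_parameter_set(evidence: GeneratedEvidence) -> ParameterSet:
    """Parameter set with UNADJUSTED incidences: plain means of the reported
    values without normalization to the reference HbA1c (for the adjusted-
    vs-unadjusted comparison)."""
    config = evidence.config
    complications = {}
    for ct in config.complications:
        cid = ct.spec.id
        pooled = pool_associations(evidence.effect_studies[cid])
        raw_mean = float(np.mean([r.incidence for r in evidence.incidence_records[cid]]))
        cost = CostEntry(mode=ct.cost_mode, amount=ct.cost_amount,
                         currency=config.currency, price_year=config.price_year,
                         horizon_years=ct.horizon_years)
        complications[cid] = ComplicationParameters(
            spec=ct.spec, a=pooled.weighted_mean,
            i_ref=min(raw_mean, 1.0) if ct.spec.recurrence == "once_only" else raw_mean,
            cost=cost, ranges=evidence.ranges[cid])
    return ParameterSet(complications=complications,
                        reference_hba1c=config.reference_hba1c)


def write_evidence_tables(evidence: GeneratedEvidence, directory: str | Path) -> dict[str, Path]:
    """Write the association and incidence evidence as delimited tables."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    assoc_rows = [
        {"source_id": s.source_id, "kind": "per_absolute", "magnitude": s.a,
         "anchor_hba1c": s.study_mean_hba1c, "baseline_risk": "",
         "person_years": s.person_years, "diabetes_type": s.diabetes_type}
        for studies in evidence.effect_studies.values() for s in studies
    ]
    inc_rows = [
        {"source_id": r.source_id, "incidence": r.incidence,
         "study_mean_hba1c": r.study_mean_hba1c, "person_years": r.person_years,
         "diabetes_type": r.diabetes_type}
        for records in evidence.incidence_records.values() for r in records
    ]
    paths = {
        "associations": directory / "associations.csv",
        "incidences": directory / "incidences.csv",
    }
    pd.DataFrame(assoc_rows).to_csv(paths["associations"], index=False)
    pd.DataFrame(inc_rows).to_csv(paths["incidences"], index=False)
    return paths


def default_demo_fixture(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete demo fixture: parameter set, cost sets, evidence tables.

    The parameter set is the generator's ground truth (so it loads with
    zero warnings against its own ranges); the "Germany" cost set is a
    synthetic example, not published data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    evidence = generate_evidence(FixtureConfig(seed=seed))
    paths: dict[str, Path] = {}
    paths["parameter_set"] = write_parameter_set(evidence.truth, directory / "parameters.json")
    costs_dir = directory / "cost_sets"
    costs_dir.mkdir(exist_ok=True)
    for cs in evidence.cost_sets:
        slug = cs.source_id.replace("/", "-")
        paths[f"costs:{cs.source_id}"] = write_cost_dataset(cs, costs_dir / f"{slug}.json")
    paths.update(write_evidence_tables(evidence, directory / "evidence"))
    manifest = {"seed": seed, "files": {k: str(v) for k, v in paths.items()}}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = directory / "manifest.json"
    return paths
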