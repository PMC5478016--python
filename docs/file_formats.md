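# File formats

## Parameter set (JSON)

One document per parameter set:

```json
{
  "reference_hba1c": 8.56,
  "population_model": "mixed",
  "complications": [
    {
      "id": "mi",
      "display_name": "Myocardial infarction",
      "category": "cardiovascular",
      "recurrence": "recurrent",
      "effect_size": 0.14,
      "incidence": 0.01,
      "cost": {"mode": "per_event", "amount": 22000.0, "currency": "EUR",
               "price_year": 2013, "horizon_years": 1},
      "ranges": {"effect_size": [0.09, 0.19], "incidence": [0.007, 0.013],
                 "cost": [15400.0, 28600.0]}
    }
  ]
}
```

- `effect_size` — fractional incidence reduction per 1% absolute HbA1c
  decrease, strictly inside (0, 1).
- `incidence` — events per patient-year at `reference_hba1c`
  (once-only complications: new cases per year among the complication-free,
  must be ≤ 1).
- `cost.mode` — `per_event` (amount already includes any follow-up over the
  horizon) or `ongoing_annual` (amount charged per year for
  `horizon_years`).
- `ranges` — optional documented literature ranges per pillar; values
  outside them load with warnings, not errors.
- `category` ∈ {cardiovascular, brain, eye, peripheral, renal};
  `recurrence` ∈ {once_only, recurrent} (fixed for esrd, blindness, mi, dka).

All ten complications (`angina, chf, mi, stroke, dka, pr, blindness,
amputation, neuropathy, esrd`) must be present for a loadable set.

## Parameter set (delimited table)

CSV with header
`complication_id, effect_size, incidence, study_hba1c, cost_amount, cost_mode, horizon_years`,
one row per complication. If `study_hba1c` is given, `incidence` is taken
to be reported at that HbA1c and is normalized to the reference on load.
Currency and price year are loader arguments (default EUR / 2013).
Identity fields (display name, category, recurrence) come from the built-in
complication registry.

## Cost data set (JSON)

```json
{
  "country": "Germany",
  "source_id": "synthetic-de",
  "currency": "EUR",
  "price_year": 2013,
  "entries": {"mi": {"mode": "per_event", "amount": 22000.0, "currency": "EUR",
                     "price_year": 2013, "horizon_years": 1}}
}
```

Exactly one entry per modeled complication; all entries share the set's
currency. A directory of such files forms a registry; selection is by
country, and by explicit `source_id` when a country has several sets.

## Association evidence table (CSV)

Header: `source_id, kind, magnitude, anchor_hba1c, baseline_risk,
person_years, diabetes_type`, where `kind` ∈ {per_absolute, per_relative,
odds_ratio}. `anchor_hba1c` is required for per_relative and odds_ratio;
`baseline_risk` (risk at the anchor) for odds_ratio. Odds ratios are stored
normalized so OR > 1 per 1% HbA1c increase.
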