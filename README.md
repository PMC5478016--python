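# hba1c-translator

A small, transparent health-economic model for clinicians, payers and
policy analysts: given an average insulin-treated diabetes population
(size, baseline HbA1c) and a planned absolute HbA1c reduction, it projects
the expected number and cost of ten diabetes-related complications and how
many events — and how much money — the reduction prevents.

## The model

Each complication is described by three pillars:

1. **Association** `a` — the constant fraction by which the complication's
   incidence falls per 1 percentage-point absolute HbA1c reduction, so that

   `I(h_target) = I(h_source) · (1 − a)^(h_source − h_target)`

   The exponent is continuous, so fractional reductions (e.g. 0.5%) work.
   Published associations arriving in other shapes (fractional change per
   10% *relative* HbA1c reduction, or an odds ratio from a logistic model)
   are converted by least-squares fitting this exponential form to their
   curve on a fine HbA1c grid, and are accepted only when the fit deviates
   less than a configurable tolerance (default 5%).

2. **Incidence** `I_ref` — events per patient-year, normalized to a common
   reference HbA1c of 8.56% using the same transfer formula. Multi-study
   incidences are averaged **unweighted** after normalization (a
   person-year weighted mean would let one mega-study dominate), while
   associations are pooled by a **person-year weighted** mean.

3. **Cost** — money per event, or an annual ongoing cost over a
   user-defined horizon of N years (dialysis-style complications). Costs
   are country-specific; a country with several published cost sets must
   be selected by explicit source, never guessed.

For a population of n patients over one year, expected events are
`n · I(baseline)` (once-only complications deplete their at-risk pool over
longer horizons: `n · (1 − (1 − I)^years)`), and prevented events are the
difference between the projection at baseline HbA1c and at
baseline − ΔHbA1c. For recurrent complications the prevented share is
exactly `1 − (1 − a)^Δ`. Supported baseline window: 6.5–11.5% HbA1c.
Only complications *positively* associated with HbA1c are covered;
severe hypoglycemia must be handled separately, and QALYs, confidence
intervals and mortality are out of scope by construction.

The evidence tables shipped here are **synthetic**: statistically
literature-like fixtures with known ground truth, generated by
`hba1c_translator.fixtures` (the parameter-recovery tests quantify how well
the pooling chain recovers that truth). Users substitute their own evidence
via the JSON/CSV formats in `docs/`.

## Worked example

```sh
python examples/01_translate.py
```

prints (synthetic demo parameters, seed 0):

```
                         complication expected_events prevented_events   expected_cost   cost_savings
angina                Angina pectoris       11.891897         0.863805    41621.640856    3023.319011
...
esrd          End-stage renal disease        1.957654         0.319763   440472.091135   71946.699679
TOTAL                           TOTAL      121.719466        13.779385  1735617.950697  210100.220076

Population: n=1000, baseline HbA1c 8.5%, reduction 0.5%, horizon 1 y (mixed model)
Expected events: 121.72   expected cost: 1,735,618 EUR
Prevented events: 13.78 [11.3%]   cost savings: 210,100 EUR [12.1%]
```

Reading: 1000 patients at baseline HbA1c 8.5% are expected to suffer
121.72 complication events this year costing €1.74M; lowering average
HbA1c by 0.5 percentage points prevents 13.78 of them (11.3% of expected
events), saving €210k (12.1% of the expected cost). The percentages are
always the rounded ratios of the absolute fields above them.

The same is available from the shell:

```sh
hba1c-translator demo --out demo --seed 0
hba1c-translator translate --params demo/parameters.json --n 1000 \
    --baseline-hba1c 8.5 --delta-hba1c 0.5 --out report
```

Other examples: `02_harmonize_evidence.py` (deviation-form conversion and
pooling), `03_sensitivity_tornado.py` (one-way ±10% sensitivity),
`04_best_worst_case.py` (all-minima/all-maxima range scenarios),
`05_population_models.py` (adjusted vs unadjusted incidence comparison).

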