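# Methods

## Model

For each of ten diabetes-related complications (angina, coronary heart
failure, myocardial infarction, stroke, diabetic ketoacidosis,
proliferative retinopathy, severe vision loss, amputation, neuropathy,
end-stage renal disease) the incidence is assumed to fall by a constant
fraction `a ∈ (0,1)` per 1 percentage-point absolute HbA1c reduction:

    I(h_t) = I(h_s) · (1 − a)^(h_s − h_t)

The exponent is continuous: the model is used with fractional reductions
such as 0.5 percentage points, and the exponential form composes exactly
across intermediate HbA1c levels. The sign convention (exponent
`h_source − h_target`) is chosen so a lower target HbA1c gives a lower
incidence; this is the single most error-prone line in the model and is
pinned by machine-precision composition and round-trip tests.

Recurrence semantics: *once-only* complications (ESRD, severe vision loss;
by configuration also CHF, proliferative retinopathy, neuropathy) count new
cases per year among patients who never had the complication, and over an
h-year horizon the at-risk pool depletes: `n·(1 − (1 − I)^h)`. *Recurrent*
complications (MI, DKA; by configuration also stroke, amputation, angina)
count total occurrences: `n·I·h`. Which of the configurable six are
once-only is a modeling choice exposed in the parameter files, not a claim;
ESRD/blindness (once-only) and MI/DKA (recurrent) are fixed by the model
definition. At the default one-year horizon the two formulas coincide.
Complications are independent — no competing risks, no interactions — and
hospitalization and mortality are deliberately not modeled because their
costs are partly embedded in the included complications (double counting).

Scope limits: average insulin-treated populations with baseline HbA1c in
6.5–11.5% (hard-checked, overridable with an explicit flag, with a floor at
6.5% after the reduction); only complications positively associated with
HbA1c, so severe hypoglycemia must be costed separately; no QALYs, no
survival modeling, no confidence intervals (the harmonization conversions
destroy the information a meta-analysis would need).

## Evidence harmonization

Published associations come in three shapes. The native form is the
fractional change per 1% absolute HbA1c. The per-relative form
(`I(H) = I0·(1−r)^(log(H/H0)/log 0.9)`, a constant fraction per 10%
relative reduction) and the odds-ratio form are converted by generating
their incidence curve on the supported HbA1c grid (6.5–11.5, step 0.05) and
fitting the native exponential by linear least squares on log incidence —
the native model is log-linear in HbA1c, so the fit is exact arithmetic,
stable, and needs no iteration. A conversion is accepted only if the fitted
curve stays within `max_rel_dev ≤ 0.05` (configurable) of the original;
rejected studies are logged and excluded from pooling rather than
distorted. The per-relative and per-absolute shapes genuinely differ by a
few percent over the full five-point window, so the gate is a real filter,
not a formality.

The odds-ratio form is underdetermined in the sources (the exact published
formula varies); it is interpreted here as a logistic risk
`p(H) = 1/(1+exp(−(β0+β1·H)))` with `β1 = ln(OR)` per 1% HbA1c and `β0`
anchored by the study's baseline risk at its mean HbA1c. ORs are stored
normalized so OR > 1 per 1% *increase*. When the anchor risk exceeds 0.10
the rare-disease OR≈RR reading degrades and a warning is emitted. At anchor
risk 0.01 the fitted `a` lands within ~1% of the rare-limit value
`1 − 1/OR` (the unit test allows 1.5% because the least-squares fit over
the whole window sees the mild logistic curvature).

Pooling: associations use the person-year weighted mean `Σ(py·a)/Σpy`; the
unweighted median and the single "representative" study (minimizing
`|a − mean| + |a − median|`, ties resolved toward the smaller effect — the
conservative, underestimating choice) are also returned, and either
convention can drive the parameter set. Incidences are first normalized to
the reference HbA1c of 8.56% (the evidence-base average) and then averaged
**unweighted**: with person-year weights a single ~600k-patient registry
study would dominate the pool.

## Parameters

| parameter | unit | default | why |
|---|---|---|---|
| `reference_hba1c` | % HbA1c | 8.56 | average of the incidence evidence base; all incidences are stored at this level |
| supported baseline window | % HbA1c | 6.5–11.5 | validity range for average insulin-treated populations |
| `horizon_years` | years | 1 | all headline outputs are per year; multi-year once-only depletion is an extension |
| fit grid | % HbA1c | 6.5–11.5 step 0.05 | fine enough that grid error ≪ fit tolerance |
| fit tolerance `max_rel_dev` | fraction | 0.05 | "close enough to the original" gate for form conversions |
| cost horizon N | years | per entry | user-defined span for ongoing-annual costs |
| sensitivity steps | — | ±10% multiplicative; baseline HbA1c ±0.5 absolute | ±0.5 is ±10% of the supported window |

Literature ranges are soft: values outside them produce structured warnings
(logged at WARN), never errors — the typical catch is a prevalence entered
where an incidence belongs. Hard bounds (a ∉ (0,1), negative costs,
once-only incidence > 1) are errors. Currency is metadata only; mixing
currencies is an error, conversion and inflation adjustment are
deliberately absent, as is discounting.

## Synthetic evidence generator

`fixtures.generate_evidence` emulates, per complication: effect-size
studies with additive Gaussian noise (sd 0.02) around a true association,
person-years log-uniform between 5·10² and 2·10⁵ (small cohorts to
registry-scale), study HbA1c uniform in 6.5–11.8%; incidence studies that
are exact realizations of the exponential model at a study HbA1c drawn
uniformly from 6.4–13.5%, times log-normal noise (σ = 0.10); and synthetic
cost sets (one Germany-like at the true amounts, three noisy US-like sets
to exercise explicit source selection). Documented ranges are min/max over
studies ∪ truth, so they always bracket the ground truth. All randomness
flows from one seed.

The ground-truth associations (0.12–0.35 per 1% HbA1c, microvascular
stronger than macrovascular), incidences (0.002–0.03 per patient-year at
the 8.56% reference) and EUR costs are plausible in magnitude but
synthetic — none are published figures, which the file labels state.

What passing tests therefore show: the harmonization/pooling/projection
chain is internally consistent and recovers known parameters under
literature-like noise (at 20 studies per pillar: pooled `a` within ±0.02
absolute, normalized incidence within ±10% relative, tolerances calibrated
once at the suite's configured seed). What they do not show: agreement with
any real evidence base, real between-study heterogeneity (systematic
design differences, diabetes-type imbalance, reporting bias), or real cost
levels.

## Numerical choices

- Log-space least squares for curve fitting (exact linear algebra, no
  optimizer, no initialization).
- Percentages: computed from unrounded totals, rounded half-up
  (`decimal.ROUND_HALF_UP`) to one decimal only in reports; a zero
  denominator yields 0.0.
- Representative-study tie-break: smaller effect size wins
  (underestimation preferred over overestimation).
- Sensitivity rows whose perturbation violates a hard bound (association
  ×1.1 ≥ 1) are reported as failed rows; the analysis continues. The one
  sanctioned clamp is baseline HbA1c ±0.5 at the window edge, logged.
- Degenerate inputs: empty study lists, missing study HbA1c, missing
  complications in a cost set, ambiguous country selection — all raise
  typed errors naming the offender.

## Known limitations

- One-year framing: multi-year projections ignore mortality, parameter
  drift and discounting; once-only depletion is the only multi-year effect
  modeled.
- The per-patient comparison table reproduces the *structure* of an
  adjusted-vs-unadjusted population-model comparison; its numbers are
  functions of the synthetic evidence, not of any published table.
- The odds-ratio conversion is one defensible reading of heterogeneous
  published formulas; studies whose covariate-adjusted shape the
  exponential cannot mimic are excluded by the fit gate rather than
  re-modeled.
- No probabilistic sensitivity analysis: perturbations are deterministic
  and one-at-a-time by design.
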