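"""Best/worst-case scenarios: all evidence at its literature extremes.

Sets every complication's incidence and association simultaneously to the
minimum (worst case for an HbA1c-lowering intervention: little to prevent)
or the maximum found in the documented ranges, and compares the spread to
the central projection — the argument for why single-source simple models
are risky.
"""

from hba1c_translator import (
    FixtureConfig,
    Population,
    generate_evidence,
    get_cost_dataset,
    prevented_events,
    project_costs,
    range_scenarios,
)

evidence = generate_evidence(FixtureConfig(seed=0))
params = evidence.truth
costs = get_cost_dataset(evidence.cost_sets, "Germany")
pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)

central_events = prevented_events(pop, params)
central_money = project_costs(central_events, costs)
worst, best = range_scenarios(pop, params, costs)

print(f"{'':12s}{'expected':>10s}{'prevented':>11s}{'cost':>14s}{'savings':>12s}")
for label, ev, mo in (("worst case", None, None), ("central", central_events, central_money),
                      ("best case", None, None)):
    if ev is None:
        r = (worst if label == "worst case" else best).results
        print(f"{label:12s}{r['expected_events']:10.2f}{r['prevented_events']:11.2f}"
              f"{r['expected_cost']:14,.0f}{r['cost_savings']:12,.0f}")
    else:
        print(f"{label:12s}{ev.total_expected:10.2f}{ev.total_prevented:11.2f}"
              f"{mo.total_expected_cost:14,.0f}{mo.total_cost_savings:12,.0f}")
print()
print("The min/max scenarios bracket the central projection component-wise;")
print("the ratio best/worst shows how far a single-source model could stray.")
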