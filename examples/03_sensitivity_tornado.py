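"""One-way sensitivity analysis: vary each input +-10%, rank by impact.

Every incidence, association and cost is perturbed one at a time by +-10%
(baseline HbA1c by +-0.5 percentage points absolute). The tornado table
ranks parameters by the spread they induce in total cost savings. Cost
perturbations never move the prevented-event count; incidence
perturbations act linearly; associations and baseline HbA1c nonlinearly.
"""

from hba1c_translator import (
    FixtureConfig,
    Population,
    generate_evidence,
    get_cost_dataset,
    one_way_sensitivity,
)
from hba1c_translator.scenario_analysis import tornado_table

evidence = generate_evidence(FixtureConfig(seed=0))
costs = get_cost_dataset(evidence.cost_sets, "Germany")
pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)

rows = one_way_sensitivity(pop, evidence.truth, costs)
table = tornado_table(rows)
print(table.head(12).round(2).to_string(index=False))
print()
print("'spread' is |savings(high) - savings(low)| in EUR; baseline HbA1c and")
print("the big-ticket complications dominate, while every ':cost' row leaves")
print("prevented_low == prevented_high == prevented_baseline untouched.")
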