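"""One-way sensitivity, best/worst-case range scenarios, model comparison."""

import numpy as np
import pytest

from hba1c_translator import (
    LiteratureRange,
    ParameterError,
    Population,
    compare_population_models,
    expected_events,
    one_way_sensitivity,
    prevented_events,
    project_costs,
    range_scenarios,
)
from hba1c_translator.scenario_analysis import tornado_table


@pytest.fixture(scope="module")
def analysis(evidence, truth_params, germany_costs):
    pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
    rows = one_way_sensitivity(pop, truth_params, germany_costs)
    return pop, rows


def rows_by_parameter(rows):
    return {row.parameter: row for row in rows}


class TestOneWaySensitivity:
    def test_cost_rows_leave_prevented_events_bit_identical(self, analysis):
        _, rows = analysis
        for row in rows:
            if row.parameter.endswith(":cost"):
                assert (row.low_result.prevented_events_total
                        == row.baseline_result.prevented_events_total)
                assert (row.high_result.prevented_events_total
                        == row.baseline_result.prevented_events_total)

    def test_cost_rows_scale_that_complications_savings_linearly(
            self, analysis, truth_params, germany_costs):
        pop, rows = analysis
        events = prevented_events(pop, truth_params)
        money = project_costs(events, germany_costs)
        by_param = rows_by_parameter(rows)
        for cid in truth_params.complications:
            row = by_param[f"{cid}:cost"]
            contribution = money.cost_savings[cid]
            assert (row.high_result.cost_savings_total
                    - row.baseline_result.cost_savings_total
                    == pytest.approx(0.1 * contribution, rel=1e-9))
            assert (row.baseline_result.cost_savings_total
                    - row.low_result.cost_savings_total
                    == pytest.approx(0.1 * contribution, rel=1e-9))

    def test_incidence_rows_scale_that_complications_contribution_linearly(
            self, analysis, truth_params):
        pop, rows = analysis
        events = prevented_events(pop, truth_params)
        by_param = rows_by_parameter(rows)
        for cid, cp in truth_params.complications.items():
            if cp.spec.recurrence != "recurrent":
                continue  # once-only depletion is linear only at horizon 1 in i0
            row = by_param[f"{cid}:incidence"]
            contribution = events.prevented[cid]
            low = row.low_result.prevented_events_total
            high = row.high_result.prevented_events_total
            base = row.baseline_result.prevented_events_total
            assert high - base == pytest.approx(0.1 * contribution, rel=1e-9)
            assert base - low == pytest.approx(0.1 * contribution, rel=1e-9)

    def test_association_rows_are_nonlinear(self, analysis):
        # deviation from the linear interpolation between the +-10% results
        _, rows = analysis
        nonlinear = 0
        for row in rows:
            if row.parameter.endswith(":association") and row.error is None:
                mid = 0.5 * (row.low_result.prevented_events_total
                             + row.high_result.prevented_events_total)
                if abs(mid - row.baseline_result.prevented_events_total) > 1e-10:
                    nonlinear += 1
        assert nonlinear > 0

    def test_higher_baseline_hba1c_prevents_strictly_more(self, analysis):
        _, rows = analysis
        row = rows_by_parameter(rows)["baseline_hba1c"]
        assert (row.high_result.prevented_events_total
                > row.baseline_result.prevented_events_total
                > row.low_result.prevented_events_total)

    def test_baseline_hba1c_response_is_convex(self, truth_params, germany_costs):
        totals = []
        for h in (7.5, 8.5, 9.5):
            pop = Population(n=1000, baseline_hba1c=h, delta_hba1c=0.5)
            totals.append(prevented_events(pop, truth_params).total_prevented)
        assert totals[1] - totals[0] < totals[2] - totals[1]

    def test_association_overflow_flags_row_without_aborting(self, truth_params,
                                                             germany_costs):
        params = truth_params.model_copy(deep=True)
        cp = params.complications["pr"]
        params.complications["pr"] = cp.model_copy(update={"a": 0.95})  # x1.1 > 1
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        rows = one_way_sensitivity(pop, params, germany_costs)
        by_param = rows_by_parameter(rows)
        assert by_param["pr:association"].error is not None
        assert by_param["mi:association"].error is None

    def test_population_model_swap_rows(self, truth_params, germany_costs, evidence):
        from hba1c_translator import pooled_parameter_set

        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        alt = {"pooled": pooled_parameter_set(evidence)}
        rows = one_way_sensitivity(pop, truth_params, germany_costs, alt_params=alt)
        row = rows_by_parameter(rows)["population_model:pooled"]
        assert row.low_result == row.high_result
        assert row.error is None

    def test_tornado_table_sorted_by_savings_spread(self, analysis):
        _, rows = analysis
        table = tornado_table(rows)
        spreads = table["spread"].dropna().to_numpy()
        assert np.all(np.diff(spreads) <= 1e-12)


class TestRangeScenarios:
    def test_degenerate_ranges_reproduce_central(self, truth_params, germany_costs):
        params = truth_params.model_copy(deep=True)
        for cid, cp in params.complications.items():
            ranges = {
                "effect_size": LiteratureRange(pillar="effect_size", complication_id=cid,
                                               low=cp.a, high=cp.a),
                "incidence": LiteratureRange(pillar="incidence", complication_id=cid,
                                             low=cp.i_ref, high=cp.i_ref),
            }
            params.complications[cid] = cp.model_copy(update={"ranges": ranges})
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        worst, best = range_scenarios(pop, params, germany_costs)
        central = prevented_events(pop, params)
        for sc in (worst, best):
            assert sc.events.total_expected == pytest.approx(central.total_expected)
            assert sc.events.total_prevented == pytest.approx(central.total_prevented)

    def test_fixture_ranges_bracket_central(self, truth_params, germany_costs):
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        worst, best = range_scenarios(pop, truth_params, germany_costs)
        central_events = prevented_events(pop, truth_params)
        central_money = project_costs(central_events, germany_costs)
        lo, hi = worst.results, best.results
        assert lo["expected_events"] <= central_events.total_expected <= hi["expected_events"]
        assert lo["prevented_events"] <= central_events.total_prevented <= hi["prevented_events"]
        assert lo["expected_cost"] <= central_money.total_expected_cost <= hi["expected_cost"]
        assert lo["cost_savings"] <= central_money.total_cost_savings <= hi["cost_savings"]

    def test_percent_prevented_differs_when_association_ranges_differ(
            self, truth_params, germany_costs):
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        worst, best = range_scenarios(pop, truth_params, germany_costs)
        assert (worst.results["percent_prevented_events"]
                != best.results["percent_prevented_events"])

    def test_missing_range_names_complication_and_pillar(self, truth_params,
                                                         germany_costs):
        params = truth_params.model_copy(deep=True)
        cp = params.complications["esrd"]
        params.complications["esrd"] = cp.model_copy(update={"ranges": {}})
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        with pytest.raises(ParameterError, match="esrd"):
            range_scenarios(pop, params, germany_costs)


class TestComparePopulationModels:
    def test_identical_sets_give_identical_columns(self, truth_params, germany_costs):
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        table = compare_population_models(
            pop, {"t1": truth_params, "t2": truth_params}, germany_costs)
        assert (table["t1"] == table["t2"]).all()

    def test_per_patient_incidence_matches_unit_projection(self, truth_params,
                                                           germany_costs):
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        table = compare_population_models(pop, {"mixed": truth_params}, germany_costs)
        unit_pop = Population(n=1, baseline_hba1c=8.5, delta_hba1c=1.0)
        unit = expected_events(unit_pop, truth_params)
        assert table.loc["total_incidence", "mixed"] == pytest.approx(unit.total_expected)

    def test_rows_are_sums_of_per_complication_values(self, truth_params,
                                                      germany_costs):
        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        table = compare_population_models(pop, {"mixed": truth_params}, germany_costs)
        unit_pop = Population(n=1, baseline_hba1c=8.5, delta_hba1c=1.0)
        events = prevented_events(unit_pop, truth_params)
        money = project_costs(events, germany_costs)
        assert table.loc["total_incidence", "mixed"] == pytest.approx(
            sum(events.expected.values()))
        assert table.loc["prevented_events_per_1pct_hba1c", "mixed"] == pytest.approx(
            sum(events.prevented.values()))
        assert table.loc["total_cost", "mixed"] == pytest.approx(
            sum(money.expected_cost.values()))
        assert table.loc["cost_savings_per_1pct_hba1c", "mixed"] == pytest.approx(
            sum(money.cost_savings.values()))

    def test_adjusted_vs_unadjusted_groups_share_shape(self, evidence, germany_costs):
        from hba1c_translator import pooled_parameter_set, raw_mean_parameter_set

        pop = Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
        adjusted = compare_population_models(
            pop, {"mixed": pooled_parameter_set(evidence)}, germany_costs)
        unadjusted = compare_population_models(
            pop, {"mixed": raw_mean_parameter_set(evidence)}, germany_costs)
        assert list(adjusted.index) == list(unadjusted.index)
        assert (adjusted["mixed"] != unadjusted["mixed"]).any()
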