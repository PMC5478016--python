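"""Exponential incidence transfer and event projections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from hba1c_translator import (
    ComplicationParameters,
    ComplicationSpec,
    CostEntry,
    IncidenceRecord,
    ParameterSet,
    Population,
    ProjectionError,
    expected_events,
    normalize_incidence,
    prevented_events,
    transfer_incidence,
)


def one_complication_set(cid="mi", recurrence="recurrent", a=0.2, i_ref=0.05,
                         reference_hba1c=8.56):
    spec = ComplicationSpec(id=cid, display_name=cid, category="cardiovascular",
                            recurrence=recurrence)
    cost = CostEntry(mode="per_event", amount=1000.0, currency="EUR", price_year=2013)
    cp = ComplicationParameters(spec=spec, a=a, i_ref=i_ref, cost=cost)
    return ParameterSet(complications={cid: cp}, reference_hba1c=reference_hba1c)


class TestTransferIncidence:
    def test_same_level_is_identity(self):
        assert transfer_incidence(0.07, 0.3, 8.5, 8.5) == 0.07

    def test_one_percentage_point_up(self):
        # closed form 0.10 / 0.8, cross-checked by one-step multiplication
        assert transfer_incidence(0.10, 0.20, 8.56, 9.56) == pytest.approx(0.125)
        one_step_down = transfer_incidence(0.125, 0.20, 9.56, 8.56)
        assert one_step_down == pytest.approx(0.125 * 0.8)

    def test_composition_equals_direct_transfer(self):
        via = transfer_incidence(transfer_incidence(0.10, 0.2, 8.56, 7.56), 0.2, 7.56, 6.56)
        direct = transfer_incidence(0.10, 0.2, 8.56, 6.56)
        assert via == pytest.approx(direct, rel=1e-15)
        assert direct == pytest.approx(0.10 * 0.8 ** 2)

    def test_effect_size_bounds(self):
        with pytest.raises(ProjectionError):
            transfer_incidence(0.1, 1.0, 8.0, 9.0)
        with pytest.raises(ProjectionError):
            transfer_incidence(0.1, 0.0, 8.0, 9.0)
        with pytest.raises(ProjectionError):
            transfer_incidence(float("nan"), 0.2, 8.0, 9.0)

    @given(st.floats(0.01, 0.99), st.floats(6.5, 11.5), st.floats(6.5, 11.5),
           st.floats(6.5, 11.5), st.floats(1e-6, 1.0))
    def test_composition_property(self, a, h1, h2, h3, i):
        via = transfer_incidence(transfer_incidence(i, a, h1, h2), a, h2, h3)
        direct = transfer_incidence(i, a, h1, h3)
        assert via == pytest.approx(direct, rel=1e-9)


class TestNormalizeIncidence:
    def test_reference_record_unchanged(self):
        rec = IncidenceRecord(incidence=0.03, study_mean_hba1c=8.56, person_years=10)
        assert normalize_incidence(rec, 0.3, 8.56) == 0.03

    def test_two_point_transfer_down(self):
        rec = IncidenceRecord(incidence=0.05, study_mean_hba1c=10.56, person_years=10)
        assert normalize_incidence(rec, 0.3, 8.56) == pytest.approx(0.05 * 0.7 ** 2)

    def test_round_trip_to_study_level(self):
        rec = IncidenceRecord(incidence=0.05, study_mean_hba1c=10.1, person_years=10)
        normalized = normalize_incidence(rec, 0.27, 8.56)
        back = transfer_incidence(normalized, 0.27, 8.56, 10.1)
        assert back == pytest.approx(0.05, rel=1e-14)

    def test_missing_study_hba1c_is_error(self):
        rec = IncidenceRecord(incidence=0.05, person_years=10)
        with pytest.raises(ProjectionError):
            normalize_incidence(rec, 0.3, 8.56)


class TestExpectedEvents:
    def test_recurrent_at_reference(self):
        params = one_complication_set()
        pop = Population(n=1000, baseline_hba1c=8.56)
        assert expected_events(pop, params).total_expected == pytest.approx(50.0)

    def test_recurrent_one_point_above_reference(self):
        params = one_complication_set()
        pop = Population(n=1000, baseline_hba1c=9.56)
        assert expected_events(pop, params).total_expected == pytest.approx(1000 * 0.05 / 0.8)

    def test_once_only_pool_depletion_vs_simulation(self):
        params = one_complication_set(cid="pr", recurrence="once_only", i_ref=0.05)
        pop = Population(n=1000, baseline_hba1c=8.56, horizon_years=3)
        got = expected_events(pop, params).total_expected
        assert got == pytest.approx(1000 * (1 - 0.95 ** 3)) == pytest.approx(142.625)
        # per-year bookkeeping oracle: deplete the complication-free pool
        free, cum = 1000.0, 0.0
        for _ in range(3):
            new = free * 0.05
            cum += new
            free -= new
        assert got == pytest.approx(cum)

    def test_once_only_equals_recurrent_at_horizon_one(self):
        once = one_complication_set(cid="pr", recurrence="once_only", i_ref=0.05)
        rec = one_complication_set(cid="mi", recurrence="recurrent", i_ref=0.05)
        pop = Population(n=1000, baseline_hba1c=8.56)
        assert expected_events(pop, once).total_expected == pytest.approx(
            expected_events(pop, rec).total_expected)

    def test_once_only_incidence_above_one_is_error(self):
        params = one_complication_set(cid="pr", recurrence="once_only",
                                      a=0.6, i_ref=0.9)
        pop = Population(n=100, baseline_hba1c=11.5)
        with pytest.raises(ProjectionError, match="pr"):
            expected_events(pop, params)

    @given(st.floats(6.6, 11.4), st.floats(0.01, 1.0))
    def test_strictly_increasing_in_baseline_hba1c(self, h, bump):
        params = one_complication_set()
        pop_lo = Population(n=100, baseline_hba1c=h)
        pop_hi = Population(n=100, baseline_hba1c=min(h + bump, 11.5))
        if pop_hi.baseline_hba1c > pop_lo.baseline_hba1c:
            assert (expected_events(pop_hi, params).total_expected
                    > expected_events(pop_lo, params).total_expected)


class TestPreventedEvents:
    def test_zero_delta_prevents_nothing(self):
        params = one_complication_set()
        pop = Population(n=1000, baseline_hba1c=9.0, delta_hba1c=0.0)
        assert prevented_events(pop, params).total_prevented == 0.0

    def test_recurrent_prevented_fraction_closed_form(self):
        params = one_complication_set(a=0.2)
        pop = Population(n=1000, baseline_hba1c=9.0, delta_hba1c=0.5)
        proj = prevented_events(pop, params)
        frac = proj.total_prevented / proj.total_expected
        assert frac == pytest.approx(1 - 0.8 ** 0.5)
        assert frac == pytest.approx(0.10557, abs=5e-6)

    def test_prevented_fraction_independent_of_iref_and_n(self):
        pop = Population(n=1000, baseline_hba1c=9.0, delta_hba1c=0.7)
        fracs = []
        for n, i_ref in ((100, 0.01), (5000, 0.2)):
            params = one_complication_set(a=0.25, i_ref=i_ref)
            proj = prevented_events(pop.model_copy(update={"n": float(n)}), params)
            fracs.append(proj.total_prevented / proj.total_expected)
        assert fracs[0] == pytest.approx(fracs[1], rel=1e-12)
        assert fracs[0] == pytest.approx(1 - 0.75 ** 0.7)

    def test_totals_are_sums_over_complications(self, truth_params, pop1000):
        proj = prevented_events(pop1000, truth_params)
        assert proj.total_prevented == pytest.approx(sum(proj.prevented.values()))
        assert proj.total_expected == pytest.approx(sum(proj.expected.values()))
        for cid in proj.expected:
            assert 0.0 <= proj.prevented[cid] <= proj.expected[cid]

    @given(st.floats(0.05, 1.5), st.floats(0.05, 1.5))
    def test_strictly_increasing_in_delta(self, d1, d2):
        lo, hi = sorted((d1, d2))
        if hi - lo < 1e-6:
            return
        params = one_complication_set()
        base = dict(n=1000.0, baseline_hba1c=9.0)
        p_lo = prevented_events(Population(**base, delta_hba1c=lo), params)
        p_hi = prevented_events(Population(**base, delta_hba1c=hi), params)
        assert p_hi.total_prevented > p_lo.total_prevented


class TestPopulationWindow:
    def test_out_of_window_baseline_rejected_without_override(self):
        with pytest.raises(ValidationError, match="6.5"):
            Population(n=100, baseline_hba1c=12.5)
        Population(n=100, baseline_hba1c=12.5, allow_out_of_range=True)

    def test_reduction_below_floor_rejected(self):
        with pytest.raises(ValidationError, match="floor"):
            Population(n=100, baseline_hba1c=6.8, delta_hba1c=0.5)
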