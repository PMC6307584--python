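"""Transition tables, Aalen-Johansen matrices, and the change-in-LOS estimand."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bedrelease.exceptions import (
    EstimandUndefinedError,
    InvalidStateError,
    ValidationError,
)
from bedrelease.multistate import (
    aalen_johansen,
    build_transition_table,
    estimate_clos,
    expected_los_given_state,
)
from bedrelease.records import PatientRecord
from bedrelease.simulate import (
    MarkovScenario,
    closed_form_clos,
    simulate_markov_cohort,
)
from conftest import ORACLE_HAZARDS, make_record


# --- transition table -----------------------------------------------------------


class TestTransitionTable:
    def test_single_trajectory(self):
        table = build_transition_table([make_record(0, 10.0, 40.0)])
        assert list(table.times) == [10.0, 40.0]
        assert table.d01[0] == 1 and table.y0[0] == 1
        assert table.d12[1] == 1 and table.y1[1] == 1
        assert table.d02.sum() == 0

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValidationError):
            build_transition_table([])

    def test_tied_discharges_share_one_event_time(self):
        table = build_transition_table(
            [make_record(0, None, 5.0), make_record(1, None, 5.0)]
        )
        assert list(table.times) == [5.0]
        assert table.d02[0] == 2 and table.y0[0] == 2

    def test_same_day_intervention_and_discharge(self):
        # the patient passes through state 1 momentarily before discharge
        table = build_transition_table([make_record(0, 7.0, 7.0)])
        assert list(table.times) == [7.0]
        assert table.d01[0] == 1 and table.d12[0] == 1
        assert table.y1[0] == 1  # at risk for the 1->2 exit at the same time

    def test_invalid_record_names_patient(self):
        bad = PatientRecord("bad-one", "intervention_era", 50.0, 40.0, True)
        with pytest.raises(ValidationError, match="bad-one"):
            build_transition_table([make_record(0, None, 5.0), bad])

    def test_censored_patients_stay_in_risk_sets(self, tiny_cohort):
        table = build_transition_table(tiny_cohort)
        # C is censored at 5 but at risk in state 0 up to and including 5
        assert list(table.times) == [2.0, 3.0, 5.0]
        assert list(table.y0) == [3, 2, 1]
        assert table.c0[2] == 1


# --- Aalen-Johansen -------------------------------------------------------------


class TestAalenJohansen:
    def test_no_events_after_origin_gives_identity(self):
        table = build_transition_table([make_record(0, None, 5.0)])
        P = aalen_johansen(table, s=10.0)
        assert np.array_equal(P.at(100.0), np.eye(3))

    def test_single_patient_certainly_discharged(self):
        table = build_transition_table([make_record(0, 10.0, 40.0)])
        P = aalen_johansen(table, s=0.0)
        assert P.at(40.0)[0, 2] == pytest.approx(1.0)

    def test_hand_computed_three_patient_product(self, tiny_cohort):
        # A: 0->1 at 2, 1->2 at 5; B: 0->2 at 3; C censored at 5.
        # P(0,5) row 0 works out to [1/3, 0, 2/3] by hand.
        P = aalen_johansen(build_transition_table(tiny_cohort), s=0.0)
        row = P.at(5.0)[0]
        assert row == pytest.approx([1 / 3, 0.0, 2 / 3], abs=1e-12)

    def test_reduces_to_kaplan_meier_without_intermediate_events(self):
        recs = simulate_markov_cohort(
            MarkovScenario(0.0, 1 / 40, 0.05, n_patients=300, seed=23,
                           censor_time=120.0)
        )
        table = build_transition_table(recs)
        P = aalen_johansen(table, s=0.0)
        p00 = P.matrices[1:, 0, 0]  # drop the identity row at s

        # independent KM: sequential product over the same event grid
        km = []
        surv = 1.0
        for k in range(table.n_times):
            if table.y0[k] > 0:
                surv = surv * (1.0 - 0.0 - table.d02[k] / table.y0[k])
            km.append(surv)
        assert np.array_equal(p00, np.array(km))  # bit-identical

        lifelines = pytest.importorskip("lifelines")
        kmf = lifelines.KaplanMeierFitter().fit(
            [r.t_end for r in recs], [r.discharged for r in recs]
        )
        ll = kmf.survival_function_at_times(table.times).to_numpy()
        assert np.allclose(p00, ll, atol=1e-12)


# --- expected LOS ----------------------------------------------------------------


class TestExpectedLOS:
    def test_no_events_runs_to_horizon(self):
        table = build_transition_table([make_record(0, None, 5.0)])
        P = aalen_johansen(table, s=10.0)
        assert expected_los_given_state(P, 10.0, 0, 60.0) == pytest.approx(60.0)

    def test_single_patient_discharged_at_forty(self):
        table = build_transition_table([make_record(0, 10.0, 40.0)])
        P = aalen_johansen(table, s=10.0)
        assert expected_los_given_state(P, 10.0, 1, 40.0) == pytest.approx(40.0)

    def test_absorbed_state_rejected(self):
        table = build_transition_table([make_record(0, 10.0, 40.0)])
        P = aalen_johansen(table, s=0.0)
        with pytest.raises(InvalidStateError):
            expected_los_given_state(P, 0.0, 2, 40.0)

    def test_state_difference_recovers_closed_form_near_zero(self):
        recs = simulate_markov_cohort(
            MarkovScenario(*ORACLE_HAZARDS, n_patients=5000, seed=29)
        )
        table = build_transition_table(recs)
        s = float(min(r.t_intervention for r in recs if r.t_intervention))
        P = aalen_johansen(table, s=s)
        tau = float(table.times[-1])
        e1 = expected_los_given_state(P, s, 1, tau)
        e0 = expected_los_given_state(P, s, 0, tau)
        # generous tolerance: one early-s evaluation, MC noise only
        assert e1 - e0 == pytest.approx(closed_form_clos(*ORACLE_HAZARDS), abs=4.0)


# --- estimand --------------------------------------------------------------------


class TestEstimateClos:
    def test_internal_consistency_and_weights(self, markov_cohort_5000):
        res = estimate_clos(markov_cohort_5000)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.weights >= 0)
        assert res.delta == pytest.approx(
            float(np.sum(res.phi * res.weights)), abs=1e-9
        )
        assert res.bed_days_released == -res.delta
        assert res.n_patients == 5000

    def test_matches_direct_aalen_johansen_route(self):
        # fast backward recursions vs explicit P(s, .) integration
        recs = simulate_markov_cohort(
            MarkovScenario(0.03, 0.02, 0.06, n_patients=80, seed=31,
                           round_days=True, censor_time=90.0)
        )
        res = estimate_clos(recs)
        table = build_transition_table(recs)
        tau = float(table.times[-1])
        for s, phi in zip(res.s_times, res.phi):
            P = aalen_johansen(table, s=float(s))
            direct = expected_los_given_state(P, float(s), 1, tau) - \
                expected_los_given_state(P, float(s), 0, tau)
            assert phi == pytest.approx(direct, abs=1e-9)

    def test_no_intermediate_events_undefined(self):
        recs = [make_record(i, None, 5.0 + i) for i in range(5)]
        with pytest.raises(EstimandUndefinedError):
            estimate_clos(recs)

    def test_everyone_intervened_at_first_time_undefined(self):
        recs = [make_record(i, 1.0, 5.0 + i) for i in range(4)]
        with pytest.raises(EstimandUndefinedError):
            estimate_clos(recs)

    def test_cohort_filter(self, markov_cohort_5000):
        pooled = estimate_clos(markov_cohort_5000)
        only = estimate_clos(markov_cohort_5000, cohort="intervention_era")
        assert only.delta == pooled.delta  # single-cohort data: same risk set
        with pytest.raises(ValidationError):
            estimate_clos(markov_cohort_5000, cohort="control")


# --- properties on random small cohorts -----------------------------------------


@st.composite
def small_cohorts(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    recs = []
    for i in range(n):
        t_end = draw(st.integers(min_value=1, max_value=12))
        if draw(st.booleans()):
            t_int = float(draw(st.integers(min_value=1, max_value=t_end)))
        else:
            t_int = None
        recs.append(make_record(i, t_int, float(t_end), draw(st.booleans())))
    return recs


@settings(max_examples=80, derandomize=True, deadline=None)
@given(small_cohorts())
def test_transition_probability_invariants(recs):
    """Row-stochastic matrices, forward-only flow, monotone absorption."""
    table = build_transition_table(recs)
    P = aalen_johansen(table, s=0.0)
    M = P.matrices
    assert np.allclose(M.sum(axis=2), 1.0, atol=1e-9)
    assert np.all((M > -1e-12) & (M < 1 + 1e-12))
    assert np.all(M[:, 1, 0] == 0) and np.all(M[:, 2, :2] == 0)
    assert np.all(np.diff(M[:, 2, 2]) >= -1e-12)
    # state-2 occupancy from any start is non-decreasing
    assert np.all(np.diff(M[:, 0, 2]) >= -1e-12)
    assert np.all(np.diff(M[:, 1, 2]) >= -1e-12)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(small_cohorts())
def test_estimand_decomposition_consistency(recs):
    """Whenever defined, weights sum to one and delta is their phi-average."""
    try:
        res = estimate_clos(recs)
    except EstimandUndefinedError:
        return
    assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(res.weights > 0)
    assert res.delta == pytest.approx(float(np.sum(res.phi * res.weights)), abs=1e-9)
    assert res.tau >= float(np.max(res.s_times))
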