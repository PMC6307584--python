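"""Synthetic-cohort generators: determinism, oracles, and calibration."""

import numpy as np
import pytest

from bedrelease.exceptions import CalibrationError, InvalidParameterError
from bedrelease.simulate import (
    MarkovScenario,
    PaperLikeScenario,
    closed_form_clos,
    markov_occupation_probability,
    simulate_markov_cohort,
    simulate_paper_like,
)


class TestMarkovCohort:
    def test_intervention_impossible_when_alpha01_zero(self):
        recs = simulate_markov_cohort(
            MarkovScenario(0.0, 0.02, 0.05, n_patients=500, seed=3)
        )
        assert all(r.t_intervention is None for r in recs)

    def test_mean_state0_sojourn_matches_exponential(self):
        # sojourn in state 0 is Exp(alpha01 + alpha02): mean 1/0.03
        recs = simulate_markov_cohort(
            MarkovScenario(0.02, 0.01, 0.05, n_patients=100_000, seed=5)
        )
        sojourn = np.array(
            [r.t_end if r.t_intervention is None else r.t_intervention for r in recs]
        )
        mc_se = sojourn.std(ddof=1) / np.sqrt(len(sojourn))
        assert abs(sojourn.mean() - 1 / 0.03) < 3 * mc_se

    def test_same_seed_reproduces_cohort(self):
        sc = MarkovScenario(0.02, 0.01, 0.05, n_patients=200, seed=11)
        assert simulate_markov_cohort(sc) == simulate_markov_cohort(sc)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha01=-0.01, alpha02=0.01, alpha12=0.05),
            dict(alpha01=0.02, alpha02=0.0, alpha12=0.05),
            dict(alpha01=0.02, alpha02=0.01, alpha12=-1.0),
        ],
    )
    def test_bad_hazards_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            simulate_markov_cohort(MarkovScenario(n_patients=10, seed=0, **kwargs))

    def test_censoring_truncates_and_flags(self):
        recs = simulate_markov_cohort(
            MarkovScenario(0.02, 0.01, 0.05, n_patients=2000, seed=7, censor_time=30.0)
        )
        assert all(r.t_end <= 30.0 for r in recs)
        assert any(not r.discharged for r in recs)
        for r in recs:
            if not r.discharged:
                assert r.t_end == 30.0
            if r.t_intervention is not None:
                assert 0 < r.t_intervention <= r.t_end

    def test_rounding_creates_valid_integer_ties(self):
        recs = simulate_markov_cohort(
            MarkovScenario(0.1, 0.05, 0.2, n_patients=500, seed=9, round_days=True)
        )
        for r in recs:
            assert r.t_end == int(r.t_end) >= 1
            if r.t_intervention is not None:
                assert r.t_intervention == int(r.t_intervention)
                assert 0 < r.t_intervention <= r.t_end
        # rounding makes same-day intervention/discharge ties appear
        assert any(r.t_intervention == r.t_end for r in recs if r.t_intervention)

    def test_occupation_fractions_match_analytic_markov(self):
        sc = MarkovScenario(0.02, 0.01, 0.05, n_patients=100_000, seed=13)
        recs = simulate_markov_cohort(sc)
        ti = np.array([np.nan if r.t_intervention is None else r.t_intervention
                       for r in recs])
        te = np.array([r.t_end for r in recs])
        ts = np.array([10.0, 30.0, 60.0])
        expected = markov_occupation_probability(sc, ts)
        n = len(recs)
        for k, t in enumerate(ts):
            in0 = np.count_nonzero((np.isnan(ti) | (ti > t)) & (te > t))
            in1 = np.count_nonzero(~np.isnan(ti) & (ti <= t) & (te > t))
            for frac, p in ((in0 / n, expected[k, 0]), (in1 / n, expected[k, 1])):
                se = np.sqrt(p * (1 - p) / n)
                assert abs(frac - p) < 3 * se


class TestClosedForm:
    def test_zero_when_discharge_hazard_unchanged(self):
        # alpha02 == alpha12 means the intervention leaves discharge dynamics
        # untouched, so the change in LOS is algebraically zero
        for a01 in (0.001, 0.02, 5.0):
            for a in (0.01, 0.3):
                assert closed_form_clos(a01, a, a) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        assert closed_form_clos(0.02, 0.01, 0.05) == pytest.approx(-26.6667, abs=1e-3)

    def test_strictly_decreasing_in_alpha12(self):
        vals = [closed_form_clos(0.02, 0.01, a12) for a12 in (0.02, 0.05, 0.2, 1.0)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_agrees_with_forced_entry_simulation(self):
        # cohort forced into the post-intervention state at admission has
        # mean LOS 1/alpha12; a natural cohort has the state-0 expression;
        # the closed form is their difference
        rng = np.random.default_rng(17)
        n = 100_000
        a01, a02, a12 = 0.02, 0.01, 0.05
        forced = rng.exponential(1 / a12, n)
        t01 = rng.exponential(1 / a01, n)
        t02 = rng.exponential(1 / a02, n)
        natural = np.where(
            t01 < t02, t01 + rng.exponential(1 / a12, n), t02
        )
        diff = forced.mean() - natural.mean()
        se = np.sqrt(forced.var() / n + natural.var() / n)
        assert abs(diff - closed_form_clos(a01, a02, a12)) < 3 * se

    def test_rejects_nonpositive_hazards(self):
        with pytest.raises(InvalidParameterError):
            closed_form_clos(0.0, 0.01, 0.05)


class TestPaperLike:
    def test_default_cohort_composition(self):
        recs = simulate_paper_like(PaperLikeScenario(seed=1))
        assert len(recs) == 112
        assert sum(r.cohort == "intervention_era" for r in recs) == 52
        assert sum(r.cohort == "control" for r in recs) == 60
        assert all(r.t_intervention is None for r in recs if r.cohort == "control")

    def test_pooled_mean_los_near_seventy(self):
        recs = simulate_paper_like(PaperLikeScenario(seed=1))
        los = np.array([r.t_end for r in recs])
        assert abs(los.mean() - 70.0) < 10.0

    def test_time_to_intervention_quartiles(self):
        recs = simulate_paper_like(PaperLikeScenario(seed=1))
        tti = np.array(
            [r.t_intervention for r in recs if r.t_intervention is not None]
        )
        assert abs(np.median(tti) - 25.0) < 10.0
        q1, q3 = np.percentile(tti, [25, 75])
        assert 3.0 < q1 < 20.0
        assert 35.0 < q3 < 70.0

    def test_demographic_margins(self):
        recs = simulate_paper_like(PaperLikeScenario(seed=2))
        ctrl = [r for r in recs if r.cohort == "control"]
        intv = [r for r in recs if r.cohort == "intervention_era"]
        assert sum(r.sex == "female" for r in ctrl) == 23
        assert sum(r.sex == "female" for r in intv) == 23
        ages_c = np.array([r.age for r in ctrl])
        ages_i = np.array([r.age for r in intv])
        assert abs(ages_c.mean() - 69) < 3 * 18 / np.sqrt(60)
        assert abs(ages_i.mean() - 74) < 3 * 14 / np.sqrt(52)

    def test_no_controls_is_allowed(self):
        recs = simulate_paper_like(PaperLikeScenario(n_control=0, seed=3))
        assert len(recs) == 52
        assert all(r.cohort == "intervention_era" for r in recs)

    def test_determinism(self):
        sc = PaperLikeScenario(seed=21)
        assert simulate_paper_like(sc) == simulate_paper_like(sc)

    def test_miscalibrated_hazards_raise_naming_the_summary(self):
        with pytest.raises(CalibrationError, match="mean length of stay"):
            simulate_paper_like(
                PaperLikeScenario(control_discharge_rate=1.0 / 300.0, seed=0)
            )
        with pytest.raises(CalibrationError, match="time to intervention"):
            simulate_paper_like(
                PaperLikeScenario(
                    alpha01=0.9, alpha02=0.1,
                    alpha12=0.1, control_discharge_rate=1.0 / 110.0, seed=0,
                )
            )
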