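import numpy as np
import pytest

from bedrelease.records import PatientRecord
from bedrelease.simulate import MarkovScenario, simulate_markov_cohort

ORACLE_HAZARDS = (0.02, 0.01, 0.05)  # alpha01, alpha02, alpha12


@pytest.fixture(scope="session")
def markov_cohort_5000():
    """Oracle scenario cohort used by the parameter-recovery checks."""
    sc = MarkovScenario(*ORACLE_HAZARDS, n_patients=5000, seed=101)
    return simulate_markov_cohort(sc)


@pytest.fixture
def tiny_cohort():
    """Three hand-checkable trajectories (one censored)."""
    return [
        PatientRecord("A", "intervention_era", 2.0, 5.0, True),
        PatientRecord("B", "intervention_era", None, 3.0, True),
        PatientRecord("C", "intervention_era", None, 5.0, False),
    ]


def make_record(i, t_int, t_end, discharged=True, cohort="intervention_era"):
    return PatientRecord(
        patient_id=f"p{i}",
        cohort=cohort,
        t_intervention=t_int,
        t_end=float(t_end),
        discharged=discharged,
    )
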