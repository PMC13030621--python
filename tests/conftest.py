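import numpy as np
import pytest

from gaitval.datamodel_io import (
    OUTCOMES,
    AnalysisConfig,
    AngleCycle,
    CohortTable,
    SubjectKey,
)
from gaitval.synthetic_gait import ErrorModel, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """2/2/2 subjects, 2 cycles, full session/operator design."""
    return simulate_cohort(2, 2, 2, cycles_per_subject=2, seed=7)


@pytest.fixture(scope="session")
def null_cohort():
    """Error-free cohort: IMU curves identical to OPTO curves."""
    return simulate_cohort(
        2, 2, 2, cycles_per_subject=2, error=ErrorModel.null(), seed=7, design="validity"
    )


def make_cycle(outcome="knee_flexion", side="left", index=0, system="OPTO", samples=None):
    if samples is None:
        samples = np.zeros(101)
    return AngleCycle(outcome, side, index, system, np.asarray(samples, dtype=float))


def make_key(subject_id="S1", group="AS", age_group="adult", session=1, operator="A"):
    return SubjectKey(subject_id, group, age_group, session, operator)


@pytest.fixture()
def tiny_table():
    """One subject, one matched pair per outcome."""
    rng = np.random.default_rng(0)
    table = CohortTable()
    key = make_key()
    for outcome in OUTCOMES:
        base = rng.normal(0, 5, 101)
        table.add(key, make_cycle(outcome, "left", 0, "OPTO", base))
        table.add(key, make_cycle(outcome, "left", 0, "IMU", base + 1.0))
    return table
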