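import numpy as np
import pytest

from trygiveup import (
    SCHEMES,
    CohortDesign,
    MatrixSpec,
    TaskConfig,
    TreatmentScheme,
    compute_rates,
    generate_cohort,
)
from trygiveup.task import GIVEUP, HIGH, LOW, TRY

COHORT_SEED = 12345  # fixed master seed for the shared default cohort


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def baseline() -> TreatmentScheme:
    return SCHEMES["baseline"]


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort, generated once per test session."""
    log, sidecar = generate_cohort(CohortDesign(master_seed=COHORT_SEED))
    return log, sidecar


@pytest.fixture(scope="session")
def cohort_rates(default_cohort):
    log, _ = default_cohort
    return compute_rates(log, window=9)


def random_small_instance(rng: np.random.Generator) -> tuple[TaskConfig, TreatmentScheme]:
    """Random tiny task + scheme for oracle-equivalence checks.

    Values, probabilities, costs and deltas are drawn freely, except that
    scheme deltas may not invert the low/high ordering within a matrix
    (the belief-state solver's stated requirement).
    """
    trials = int(rng.integers(1, 5))
    specs = {}
    for matrix in (TRY, GIVEUP):
        low = float(np.round(rng.uniform(-2, 3), 2))
        high = low + float(np.round(rng.uniform(0, 13), 2))
        specs[matrix] = MatrixSpec(low, high, float(np.round(rng.uniform(0, 1), 3)),
                                   int(rng.integers(1, 4)))
    config = TaskConfig(
        try_spec=specs[TRY],
        giveup_spec=specs[GIVEUP],
        trials_per_round=trials,
        analysis_window=trials,
    )
    while True:
        deltas = {
            (m, lvl): float(rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0]))
            for m in (TRY, GIVEUP)
            for lvl in (LOW, HIGH)
        }
        ok = all(
            specs[m].high_value + deltas[(m, HIGH)]
            >= specs[m].low_value + deltas[(m, LOW)]
            for m in (TRY, GIVEUP)
        )
        if ok:
            break
    costs = {m: float(np.round(rng.uniform(0, 3), 2)) for m in (TRY, GIVEUP)}
    return config, TreatmentScheme("random", deltas, costs)
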