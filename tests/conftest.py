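import numpy as np
import pandas as pd
import pytest

from nccvalidate import CensoringSpec, CohortConfig, simulate_cohort


@pytest.fixture
def toy_cohort():
    """Five subjects: cases A (t=1) and B (t=3), controls C, D, E
    censored at 4, 2 and 5.  Risk sets can be enumerated by hand."""
    return pd.DataFrame(
        {
            "subject_id": ["A", "B", "C", "D", "E"],
            "time": [1.0, 3.0, 4.0, 2.0, 5.0],
            "event": [1, 1, 0, 0, 0],
            "sex": [0, 1, 0, 1, 0],
        }
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderate cohort under the default configuration (rare outcome,
    sex-dependent censoring); shared across tests for speed."""
    return simulate_cohort(CohortConfig(n_subjects=3000, seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with a higher event rate, convenient for repeated
    NCC sampling in Monte-Carlo checks."""
    config = CohortConfig(
        n_subjects=120,
        baseline_scale=1.0 / 0.02,
        censoring=CensoringSpec(by="sex", rates={0: 0.08, 1: 0.04}),
        seed=3,
    )
    return simulate_cohort(config)


@pytest.fixture
def survival_data():
    """Random censored survival data with continuous (tie-free) times and
    risks, for comparisons against reference implementations."""
    rng = np.random.default_rng(11)
    n = 150
    times = rng.exponential(5.0, n)
    cens = rng.exponential(7.0, n)
    return {
        "times": np.minimum(times, cens),
        "events": (times <= cens).astype(int),
        "risks": rng.uniform(0.01, 0.9, n),
        "weights": rng.uniform(0.5, 4.0, n),
    }
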