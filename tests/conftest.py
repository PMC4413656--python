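import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import episcore as ep

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(time, event, sample_ids=None, **extra_cols):
    """Build a SurvivalCohort from raw arrays (test helper)."""
    time = np.asarray(time, float)
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(len(time))]
    df = pd.DataFrame(
        {"time_months": time, "event": np.asarray(event, int), **extra_cols},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ep.SurvivalCohort(df)


def random_survival(rng, n, hazard=0.02, beta=0.0, x=None, censor_scale=100.0):
    """Exponential survival with optional binary/continuous effect; tie-free."""
    lam = hazard * np.exp(beta * (x if x is not None else 0.0)) * np.ones(n)
    t_event = rng.exponential(1.0 / lam)
    c = rng.uniform(0, censor_scale, n)
    time = np.maximum(np.minimum(t_event, c), 1e-9)
    event = (t_event <= c).astype(int)
    return time, event


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small survival cohort with one strong planted probe (shared fixture)."""
    spec = ep.CohortSimSpec(
        n_patients=150,
        n_probes=25,
        planted_effects={0: (0.5, float(np.log(3)))},
        censor_rate=0.3,
        seed=42,
    )
    matrix, cohort, truth = ep.gen_survival_cohort(spec)
    return matrix, cohort, truth
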