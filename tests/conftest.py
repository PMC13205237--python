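import numpy as np
import pytest

from mzlprog import synthetic as syn


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted marker effects (markers independent of survival)."""
    df, _ = syn.generate_cohort(syn.CohortSpec(n_patients=200, seed=11))
    return df


@pytest.fixture(scope="session")
def mature_cohort_spec():
    """Planted protective hazard step exp(-0.9) above CD21 = 50% in a cohort
    with mature follow-up (~40% OS events), used by recovery experiments."""

    def make(seed: int, n_patients: int = 400) -> syn.CohortSpec:
        return syn.CohortSpec(
            n_patients=n_patients,
            seed=seed,
            baseline_hazard=0.007,
            censor_rate=0.006,
            admin_horizon=150.0,
            threshold_effects_os={"CD21": (50.0, -0.9)},
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
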