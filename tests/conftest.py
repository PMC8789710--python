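import numpy as np
import pytest

from pvloop import (
    VariabilityParams,
    generate_cohort,
    simulate_recording,
)
from pvloop.cohortstats import cohort_table


@pytest.fixture(scope="session")
def quiet_sim():
    """Deterministic noise-free stenotic recording with its ground truth."""
    return simulate_recording(variability=VariabilityParams.quiet(), duration=20.0)


@pytest.fixture(scope="session")
def preload_sim():
    """Noise-free recording with preload variability (regressions possible)."""
    var = VariabilityParams(rr_cv=0.03, preload_sd=0.8, noise_p_sd=0.0,
                            noise_v_sd=0.0, seed=11)
    return simulate_recording(variability=var, duration=25.0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic 8-patient paired pre/post cohort (fixed seed)."""
    return generate_cohort(n_patients=8, seed=7)


@pytest.fixture(scope="session")
def default_cohort_table(default_cohort):
    return cohort_table(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
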