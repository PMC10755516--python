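import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirdose as md

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lu177():
    return md.LU177


@pytest.fixture(scope="session")
def smatrix():
    return md.default_smatrix()


@pytest.fixture(scope="session")
def noisy_cohort():
    """One default cohort at the study's noise conditions."""
    return md.generate_cohort(md.CohortDesign(seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free cohort with identical kinetics across cycles."""
    from mirdose.simulate import KineticPrior

    return md.generate_cohort(md.CohortDesign(seed=5), KineticPrior().noiseless())


def mono_measurements(a0, rate, times, patient="P", region="kidneys", cycle=1):
    return [
        md.ActivityMeasurement(patient, cycle, region, t, a0 * np.exp(-rate * t))
        for t in times
    ]
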