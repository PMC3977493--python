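import numpy as np
import pytest

import rygbtraj as rt


@pytest.fixture(scope="session")
def published_ms() -> rt.ModelSet:
    return rt.published_model()


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=4000 synthetic cohort from the published truth, default conditions."""
    return rt.generate_cohort(rt.CohortSpec(n_patients=4000, seed=11))


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort) -> rt.ModelSet:
    return rt.fit_modelset(recovery_cohort)


@pytest.fixture(scope="session")
def retention_cohort():
    """n=10000 default-condition cohort for attrition checks."""
    return rt.generate_cohort(rt.CohortSpec(n_patients=10000, seed=29))


@pytest.fixture(scope="session")
def fidelity_bmis():
    """5000 simulated BMIs at exactly (bmi0=50, age=50, t=6 months)."""
    spec = rt.CohortSpec(
        n_patients=5000,
        seed=7,
        age_mean=50.0,
        age_sd=0.0,
        bmi_mean=50.0,
        bmi_sd=0.0,
        schedule=(6.0,),
        attrition_targets=None,
        jitter_days=0.0,
    )
    cohort = rt.generate_cohort(spec)
    merged = cohort.measurements.merge(cohort.profiles[["patient_id", "height_m"]])
    return (merged["weight_kg"] / merged["height_m"] ** 2).to_numpy()


@pytest.fixture(scope="session")
def screening_cohort():
    """Mid-size cohort where only baseline BMI and age drive trajectories."""
    return rt.generate_cohort(rt.CohortSpec(n_patients=1500, seed=5))


@pytest.fixture(scope="session")
def small_cohort():
    return rt.generate_cohort(rt.CohortSpec(n_patients=40, seed=3))
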