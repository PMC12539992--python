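import numpy as np
import pytest

from akiscore.cohort import PatientRecord
from akiscore.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort of 400 patients, fixed seed, shared across tests."""
    cohort, p_true = generate_cohort(GeneratorConfig(n=400), seed=7)
    return cohort, p_true


@pytest.fixture(scope="session")
def medium_cohort():
    cohort, p_true = generate_cohort(GeneratorConfig(n=1785), seed=11)
    return cohort, p_true


def make_record(pid="p0", **overrides):
    kwargs = dict(
        id=pid, age=60, sex="M", weight_kg=60.0, albumin_gdl=4.0,
        cddp_dose_mg=100.0, hypertension=False, diabetes=False,
        mg_supplement=True, infusion_volume_l=4.0, infusion_duration_h=6.0,
        scr_baseline=0.7, scr_followup_max14d=0.8, drugs={},
    )
    kwargs.update(overrides)
    return PatientRecord(**kwargs)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
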