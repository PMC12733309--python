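import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from limbrisk import (
    default_generator_config,
    generate_cohort,
    panel_frame,
)


@pytest.fixture(scope="session")
def study_cohort():
    """One seeded synthetic cohort at the study size (n=110)."""
    return generate_cohort(default_generator_config(seed=20230226))


@pytest.fixture(scope="session")
def merged_frame(study_cohort):
    """Cohort raw fields merged with the computed biomarker panel."""
    base = study_cohort.to_frame()
    return base.merge(panel_frame(study_cohort), on="subject_id")
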