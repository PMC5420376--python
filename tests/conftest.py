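import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jointplay.curves import extract_features, features_frame
from jointplay.generator import (
    CohortSpec,
    LimbComplianceParams,
    ProtocolConfig,
    generate_cohort,
)
from jointplay.metrics import build_analysis_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def symmetric_params():
    """The worked exponential limb: S=1 Nm, beta=0.05/deg, h=0.25 Nm."""
    return LimbComplianceParams(
        scale_er=1.0, scale_ir=1.0, shape_er=0.05, shape_ir=0.05,
        hysteresis_offset=0.25, torque_noise_sd=0.0, angle_step=0.05,
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped synthetic cohort: 9/6/2 subjects, default means."""
    return generate_cohort(CohortSpec(seed=20250928))


@pytest.fixture(scope="session")
def study_analysis(study_cohort):
    """Per-limb analysis table (with pivot grades) of the study cohort."""
    feats = {
        (r.subject_id, r.limb_status): extract_features(r)
        for r in study_cohort.recordings()
    }
    cohort_df = study_cohort.cohort_frame()
    analysis = build_analysis_table(cohort_df, features_frame(feats))
    return analysis.merge(
        cohort_df[["subject_id", "limb", "pivot_shift_grade"]],
        on=["subject_id", "limb"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
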