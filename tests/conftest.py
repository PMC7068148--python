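import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject default-scenario cohort shared across integration tests."""
    from qeeg.simulate import default_scenario, generate_cohort

    return generate_cohort(default_scenario(seed=42), 6)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    from qeeg.features import FeatureConfig, extract_features
    from qeeg.preprocess import PreprocessConfig, derive_bipolar, segment_stages
    from qeeg.stats import average_stage_features

    epoch_sets = []
    for rec in small_cohort:
        epoch_sets.extend(segment_stages(derive_bipolar(rec), PreprocessConfig()))
    return average_stage_features(extract_features(epoch_sets, FeatureConfig()))
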