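import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from semgsel import (FeatureMatrix, Recording, SimConfig, WindowSpec,
                     build_feature_matrix, generate_recording)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Small but realistic generator conditions shared by the fast tests:
#: full channel/gesture counts, shorter trials.
SMALL_SIM = dict(n_channels=8, n_classes=7, trials_per_class=6,
                 trial_duration=1.0)


@pytest.fixture(scope="session")
def small_recording() -> Recording:
    return generate_recording(SimConfig(seed=11, **SMALL_SIM))


@pytest.fixture(scope="session")
def small_features(small_recording) -> FeatureMatrix:
    return build_feature_matrix(small_recording, WindowSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
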