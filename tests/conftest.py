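import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_atlas():
    from liminal import synth

    specs = [
        synth.RoiSpec("vis", "cortical_activated", 60),
        synth.RoiSpec("dmn", "cortical_deactivated", 50),
        synth.RoiSpec("thal", "subcortical", 40),
    ]
    return synth.make_roi_geometry((14, 14, 14), specs)


@pytest.fixture(scope="session")
def small_dataset(small_atlas):
    """One subject, 6 runs, default ground truth."""
    from liminal import synth

    rng = np.random.default_rng(7)
    truth = synth.GroundTruth()
    table = synth.simulate_behavior(synth.make_session(6, rng), truth, rng)
    return synth.make_beta_dataset(table, small_atlas, truth, rng)
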