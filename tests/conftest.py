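import numpy as np
import pytest

from hippoctx import build_association_set
from hippoctx.experiments import StudyConfig
from hippoctx.netcore import LearningConfig, SettleConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def assoc():
    """Default-size world: 120 objects, 40 contexts, 3 objects per context."""
    return build_association_set(rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_study():
    """Miniature study for plumbing tests: trains in well under a second."""
    return StudyConfig(
        n_contexts=4,
        objects_per_context=3,
        epochs=2,
        dg_size=64,
        ca3_size=32,
        ca1_size=32,
        settle=SettleConfig(max_cycles=8),
        learning=LearningConfig(),
    )


@pytest.fixture(scope="session")
def tiny_assoc(tiny_study):
    return tiny_study.world(np.random.default_rng(11))
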