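import numpy as np
import pytest

from funmstate.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 default cohort with ground truth, shared across tests."""
    subjects, truth = generate_cohort(SimConfig(n_subjects=300), seed=7)
    return subjects, truth


@pytest.fixture(scope="session")
def marker_cohort():
    """n=500 cohort with the 11-scale joint marker generator attached."""
    cfg = SimConfig(n_subjects=500).with_markers()
    subjects, truth = generate_cohort(cfg, seed=11)
    return subjects, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
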