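import numpy as np
import pytest

from exprbench.preprocess import filter_probesets
from exprbench.simulate import StudySimConfig, simulate_study


@pytest.fixture(scope="session")
def strong_study():
    """Filtered study with a strong planted signal (50 DE probesets, 3 SD)."""
    cfg = StudySimConfig(
        study_id="strong", n1=30, n2=30, p=500, n_de=50, delta=3.0, seed=5
    )
    study, _ = filter_probesets(simulate_study(cfg))
    return study


@pytest.fixture(scope="session")
def null_study():
    """Balanced study with no signal at all."""
    cfg = StudySimConfig(study_id="null", n1=20, n2=20, p=200, n_de=0, seed=7)
    study, _ = filter_probesets(simulate_study(cfg))
    return study


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
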