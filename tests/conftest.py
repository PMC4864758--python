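import numpy as np
import pytest

from cuefusion import CohortSpec, ObserverParams, ViewingGeometry


@pytest.fixture
def geom():
    return ViewingGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def equal_observer():
    """Mandatory-fusion observer with equal cue reliabilities."""
    return ObserverParams(sigma_T=4.0, sigma_D=4.0, sigma_c=0.0,
                          regime="mandatory_fusion")


@pytest.fixture
def study_spec():
    """Study-faithful synthetic cohort: 16 selective + 14 mandatory subjects."""
    return CohortSpec(seed=2024)
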