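import numpy as np
import pytest

from pumetrics import case_study_model


@pytest.fixture(scope="session")
def model():
    """Default two-Gaussian case-study model: N(-1,1) vs N(1,1),
    beta=3/4, c=1/10, prior pi=3/10 (alpha=1/4 via the mixture identity)."""
    return case_study_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
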