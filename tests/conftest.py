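import numpy as np
import pytest

from microzone import FeedbackParams, PopulationLayout, RuleParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def layout():
    return PopulationLayout()


@pytest.fixture
def inertia_params():
    return RuleParams(k=0.1, variant="inertia")


@pytest.fixture
def adjusted_params():
    return RuleParams(k=0.1, b=0.5, variant="inertia_adjusted")


@pytest.fixture
def fb_params():
    return FeedbackParams(f_coeff=0.8)
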