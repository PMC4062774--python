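import numpy as np
import pytest

from optcut import YoudenWeights


@pytest.fixture(scope="session")
def weights():
    """Balanced study: prevalence 0.5, NB/NC = 1, hence R = 1."""
    return YoudenWeights(0.5, 1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240614)
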