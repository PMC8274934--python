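import numpy as np
import pytest

from fisbkit.neck_model import reference_params


@pytest.fixture(scope="session")
def dot_params():
    """The reference parameter point of the neck stability analysis."""
    return reference_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
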