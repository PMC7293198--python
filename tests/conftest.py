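import numpy as np
import pytest

from tcesim import BindingParams


@pytest.fixture
def params():
    """Cibisatamab-like default binding parameters."""
    return BindingParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_binding_params(rng):
    """A physically plausible random draw of binding parameters."""
    return BindingParams(
        kon_ceatce=10 ** rng.uniform(-5, -3),
        koff_ceatce=10 ** rng.uniform(-4, -1),
        kon_cd3tce=10 ** rng.uniform(-5, -3),
        koff_cd3tce=10 ** rng.uniform(-5, -2),
        lambda_crossarm=10 ** rng.uniform(0, 4),
        cea_sites=10 ** rng.uniform(3, 6),
        cd3_sites=10 ** rng.uniform(4, 5.1),
        soluble_cea=float(rng.uniform(0, 5)),
    )
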