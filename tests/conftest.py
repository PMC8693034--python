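import numpy as np
import pytest

from trxgeom.synthetic import make_target


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def target48():
    """One canonical synthetic target (L=48, moderate MSA) shared by tests."""
    return make_target(L=48, seed=11, depth=80)


@pytest.fixture(scope="session")
def target_with_templates():
    return make_target(L=32, seed=5, depth=40, n_templates=3,
                       template_noise=0.3, template_coverage=0.8)
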