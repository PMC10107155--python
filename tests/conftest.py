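import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from achiasmate.genome import default_table, mini_table
from achiasmate.meiosis_model import LossParams, compute_bias
from achiasmate.synthetic_wgs import generate_snp_table


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def mini():
    return mini_table()


@pytest.fixture(scope="session")
def unbiased(table):
    """Unbiased MI segregation (all x_N = 0.5) on the full-length genome."""
    return compute_bias(table)


@pytest.fixture(scope="session")
def fitted_loss():
    """The loss parameters estimated from the observed ascus fractions."""
    return LossParams(pa=0.017, pb=0.013)


@pytest.fixture(scope="session")
def snp_table(mini):
    """A hybrid SNP map at 0.7% density on the miniature genome."""
    return generate_snp_table(mini, density=0.007, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
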