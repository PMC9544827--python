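import numpy as np
import pytest

from screenmin import PValueTable, load_navy_metabolites


@pytest.fixture
def toy3():
    """Three pairs with (pmin, pmax) = (0.001, 0.002), (0.01, 0.9), (0.3, 0.4)."""
    return PValueTable([0.001, 0.9, 0.3], [0.002, 0.01, 0.4])


@pytest.fixture
def toy4_pmin():
    """pmin = (0.001, 0.01, 0.02, 0.5) with uninformative large pmax."""
    return PValueTable([0.001, 0.01, 0.02, 0.5], [0.9, 0.95, 0.99, 0.98])


@pytest.fixture(scope="session")
def navy():
    """The packaged 22-metabolite table (from a screen of 149 candidates)."""
    return load_navy_metabolites()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_table(rng, m, frac_signal=0.3, snr=2.5):
    """A random m x 2 p-value table with a mix of null and shifted entries."""
    z = rng.standard_normal((m, 2))
    signal = rng.random((m, 2)) < frac_signal
    z[signal] += snr
    from scipy.stats import norm

    p = norm.sf(z)
    return PValueTable(p[:, 0], p[:, 1])
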