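import numpy as np
import pytest

from proteokin import reference, simulate
from proteokin.twostate import dose_response


@pytest.fixture(scope="session")
def modulator_grid():
    """Default assay grid: 0 plus nine log-spaced points over 0.1-10 uM."""
    return simulate.default_modulator_grid()


@pytest.fixture(scope="session")
def tmpc_dose_response(modulator_grid):
    """Noiseless dose response of the biphasic corrole archetype."""
    return dose_response(reference.TMPC_LIKE, modulator_grid)


@pytest.fixture(scope="session")
def trist4_dose_response(modulator_grid):
    """Noiseless dose response of the pure-activator archetype."""
    return dose_response(reference.TRIS_T4_LIKE, modulator_grid)


@pytest.fixture(scope="session")
def fixture_suite():
    """The five canonical synthetic datasets, generated once per session."""
    return simulate.generate_fixture_suite(seed=11)


def random_twostate(rng, n_sites=None, m_sites=None):
    """Draw a random valid two-state parameter set for property tests."""
    from proteokin.twostate import TwoStateParameters

    def logu(lo, hi):
        return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))

    n = int(rng.integers(0, 4)) if n_sites is None else n_sites
    m = int(rng.integers(0, 2)) if m_sites is None else m_sites
    return TwoStateParameters(
        kcat_a=logu(1e-2, 1e2),
        kcat_b=logu(1e-2, 1e2),
        km_a=logu(1e-6, 1e-3),
        km_b=logu(1e-6, 1e-3),
        l_u=logu(1e-3, 1e3),
        l_l=logu(1e-3, 1e3),
        k_au=logu(1e4, 1e8),
        k_al=logu(1e4, 1e8),
        k_bu=logu(1e4, 1e8),
        k_bl=logu(1e4, 1e8),
        k_ai=logu(1e4, 1e8) if m > 0 else 0.0,
        k_bi=logu(1e4, 1e8) if m > 0 else 0.0,
        n_sites=n,
        m_sites=m,
    )
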