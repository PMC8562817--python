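import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def ar1_region_factory():
    """Factory for small whitened regions with ar1 LD and simulated effects."""
    from regpoly.ld import factorize, whiten
    from regpoly.simulate import (
        SimulationSpec,
        draw_architecture,
        make_ld,
        simulate_sumstats,
    )

    def make(m=5, rho=0.5, p_r=0.3, h2_r=0.1, n=2000, seed=0):
        fac = factorize(make_ld("ar1", m, rho=rho))
        gen = np.random.default_rng(seed)
        spec = SimulationSpec(p_r=p_r, h2_r=h2_r, n=n, m_r=m, rho=rho, seed=seed)
        c, beta = draw_architecture(spec, gen)
        beta_hat = simulate_sumstats(beta, fac, h2_r, n, gen)
        region = whiten(beta_hat, fac, n=n, h2_r=h2_r)
        return region, c, beta

    return make
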