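import logging

import numpy as np
import pytest

import varclm as v

logging.getLogger("varclm").setLevel(logging.ERROR)

# Test-scale sampler settings: two chains and 1,200 iterations mix well on the
# ~2,200-record emulated dataset (all PSRF < 1.05) while keeping each shared
# fit to a few seconds.
TEST_SAMPLER = dict(n_chains=2, n_iter=1200, n_burnin=600)


@pytest.fixture(scope="session")
def emulated_ds():
    """Default emulated dataset: 2,210 records, published class structure."""
    return v.emulate_insight(v.EmulationSpec(seed=0))


@pytest.fixture(scope="session")
def emulated_fit(emulated_ds):
    """One shared posterior fit on the emulated dataset."""
    draws = v.fit_bayes(emulated_ds, v.SamplerConfig(seed=1, **TEST_SAMPLER))
    assert draws.converged
    return draws


@pytest.fixture(scope="session")
def structural_ds():
    """Emulated dataset plus 15 mis-scaled structural (class 5, HIGH) records."""
    return v.concat(v.emulate_insight(v.EmulationSpec(seed=0)), v.make_structural_fixture(15, seed=0))


@pytest.fixture(scope="session")
def structural_fit(structural_ds):
    draws = v.fit_bayes(structural_ds, v.SamplerConfig(seed=1, **TEST_SAMPLER))
    assert draws.converged
    return draws


@pytest.fixture
def simple_params():
    """Symmetric five-class model with no covariate effect."""
    return v.CLMParameters(theta=[-2.0, -1.0, 1.0, 2.0], beta=[0.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
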