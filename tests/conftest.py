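import warnings

import pytest

from cetrepro.simulate import SyntheticConfig, simulate_population


@pytest.fixture(autouse=True)
def _quiet_mcmc_warnings():
    # convergence flags are exercised explicitly where relevant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", FutureWarning)
        yield


@pytest.fixture(scope="session")
def sim_default():
    """Paper-scale synthetic population (n=106) with its truth ledger."""
    return simulate_population(SyntheticConfig(seed=11, n_females=106))


@pytest.fixture(scope="session")
def sim_large():
    """Larger synthetic population for lower-variance checks."""
    return simulate_population(SyntheticConfig(seed=7, n_females=600))
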