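import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnvrecur as cr

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cover_toy():
    """3 calls over a 5-probe grid: the worked example for the per-probe
    statistics (confidences 10, 5, 1)."""
    return cr.make_toy_fixture("cover_toy")


@pytest.fixture(scope="session")
def figure2():
    """One common region supported by two clearly separated call pairs."""
    return cr.make_toy_fixture("figure2")


@pytest.fixture(scope="session")
def small_population():
    """A 20-locus, 100-sample simulated study reused across tests."""
    loci = cr.default_locus_specs(20)
    calls, groups, truth = cr.simulate_population(loci, 100, noise_rate=0.5,
                                                  seed=7)
    return loci, calls, groups, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20100322)
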