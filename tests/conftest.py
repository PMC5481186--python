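import numpy as np
import pytest

from pirnapipe import SimParams, build_reporter, simulate_biogenesis


@pytest.fixture(scope="session")
def params():
    return SimParams(depth=8000, seed=11)


@pytest.fixture(scope="session")
def reporter(params):
    return build_reporter(params)


@pytest.fixture(scope="session")
def simulation(reporter, params):
    """(fragments, truths) for the default control-like genotype."""
    return simulate_biogenesis(reporter, params, np.random.default_rng(params.seed))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
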