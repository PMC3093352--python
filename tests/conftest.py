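import numpy as np
import pytest

import photoepistasis as pe


@pytest.fixture(scope="session")
def reference():
    return pe.reference_parameters()


@pytest.fixture(scope="session")
def network(reference):
    return pe.build_network(reference)


@pytest.fixture(scope="session")
def ref_ensemble(network):
    """Reference-genotype quantum-bump ensemble shared across trait tests."""
    return pe.simulate_ensemble(network, n_trials=300, base_seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
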