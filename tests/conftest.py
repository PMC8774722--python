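import numpy as np
import pytest

from shellperc import LatticeSpec, assign_shells, removal_probabilities


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def make_order_inputs(L, n_shells, r):
    spec = LatticeSpec(L, n_shells)
    return spec, assign_shells(spec), removal_probabilities(r, n_shells)
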