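import pytest

from redoxpoise import ToySpec, make_toy_chain, make_toy_redox_cell
from redoxpoise.pco import PcoHyperparams


@pytest.fixture
def chain2():
    """A = M = B with Keq (10, 1), ends fixed at 1 M: [M]* = sqrt(10)."""
    return make_toy_chain(ToySpec(length=2, keqs=(10.0, 1.0), include_growth=True))


@pytest.fixture
def redox_cell():
    return make_toy_redox_cell()


@pytest.fixture
def hp():
    # roomy default cap so the chain fixture's sqrt(10) M optimum is interior
    return PcoHyperparams(n_max=10.0)
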