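import numpy as np
import pytest

from gapscale.config import default_circuit_params
from gapscale.genecircuit import CircuitParams


@pytest.fixture(scope="session")
def default_circuit():
    """(params, bcd, schedule, external inputs) of the shipped default set."""
    return default_circuit_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_params(ng: int = 2, **overrides) -> CircuitParams:
    """A minimal well-formed parameter set for tiny circuit instances."""
    genes = tuple(f"g{i}" for i in range(ng))
    base = dict(
        R=np.full(ng, 10.0),
        D=np.full(ng, 0.5),
        delta=np.full(ng, 0.2),
        T=np.zeros((ng, ng)),
        m=np.zeros(ng),
        E=np.zeros((ng, 2)),
        h=np.zeros(ng),
        genes=genes,
    )
    base.update(overrides)
    return CircuitParams(**base)


@pytest.fixture()
def tiny_params():
    return make_params()
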