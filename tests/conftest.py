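import numpy as np
import pytest

from erbbqsp.network_model import (
    ParameterSet,
    Protocol,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
    build_erbb_network,
)


@pytest.fixture(scope="session")
def default_network():
    return build_erbb_network()


@pytest.fixture(scope="session")
def hrg_protocol():
    """30 min equilibration, 1 nmol/l HRG, 2 h readout window."""
    return Protocol(
        30.0,
        events=((0.0, "HRG", 1.0, "add"),),
        readout_times=tuple(np.arange(0.0, 121.0, 5.0)),
    )


def make_binding_toy(a0=100.0, b0=60.0, kf=0.02, kr=0.5):
    """A + B <-> C in one compartment; closed-form equilibrium exists."""
    params = ParameterSet()
    params.set("kf", kf, "1/(molec/cell)/min", "")
    params.set("kr", kr, "1/min", "")
    species = [
        SpeciesDef("A", "membrane", a0),
        SpeciesDef("B", "membrane", b0),
        SpeciesDef("C", "membrane", 0.0),
    ]
    reactions = [Reaction((("A", 1), ("B", 1)), (("C", 1),), "kf", "kr", "binding")]
    return ReactionNetwork(species, reactions, params, {"C": {"C": 1.0}})


@pytest.fixture
def binding_toy():
    return make_binding_toy()
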