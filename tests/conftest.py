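from fractions import Fraction

import pytest

from phbcascade.kinetics import (KineticParameters, ReactionParams,
                                 ScenarioSpec, shipped_params)
from phbcascade.network import Network, Reaction, Species, build_network


def make_network(species_roles, reactions, variant="toy"):
    """Compact toy-network builder.

    ``species_roles``: {id: "internal"|"boundary"};
    ``reactions``: [(id, {species: coeff}, reversible), ...].
    """
    sp = tuple(Species(id=s, name=s, role=r) for s, r in species_roles.items())
    rx = tuple(
        Reaction(id=rid, name=rid,
                 stoich={s: Fraction(c) for s, c in st.items()}, reversible=rev)
        for rid, st, rev in reactions
    )
    return Network(species=sp, reactions=rx, variant=variant)


@pytest.fixture(scope="session")
def full_net():
    return build_network("full")


@pytest.fixture(scope="session")
def model1():
    return shipped_params("model1")


@pytest.fixture(scope="session")
def model1_5x(model1):
    vm = {rid: 5.0 for rid in model1.reactions}
    vm["FPK"] = 0.6
    return model1.with_vmax(vm)


@pytest.fixture(scope="session")
def scenario_240():
    return ScenarioSpec(t_end=240.0)


# --- small two-enzyme cascade: MD -> X -> PHB (fast to simulate) ----------

@pytest.fixture(scope="session")
def toy_cascade():
    net = make_network(
        {"MD": "boundary", "X": "internal", "PHB": "boundary"},
        [("E1", {"MD": -1, "X": 1}, False),
         ("E2", {"X": -1, "PHB": 1}, False)],
    )
    # E2 is the bottleneck so the intermediate pool X accumulates and both
    # Km values shape the observable curves (strong identifiability); the
    # concentration and Vmax magnitudes match the study scale (100 mM
    # substrate, ~1 mM/min rates) so the transient spans hours
    params = KineticParameters({
        "E1": ReactionParams(vmax=1.0, km={"MD": 30.0}),
        "E2": ReactionParams(vmax=0.6, km={"X": 5.0}),
    })
    scenario = ScenarioSpec(initial={"MD": 100.0}, t_end=480.0,
                            residual_fraction=1.0, label="toy")
    return net, params, scenario
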