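import pytest

import crowdfba as cf


@pytest.fixture(scope="session")
def toy():
    """Default (Warburg-generating) toy central-carbon fixture."""
    return cf.make_toy_network()


@pytest.fixture(scope="session")
def toy_aa():
    """Toy fixture extended with glutamine/glutamate/alanine routes."""
    return cf.make_toy_network(cf.ToyNetworkSpec(with_amino_acids=True))


@pytest.fixture(scope="session")
def uniform_toy():
    """Uniform-cost negative control (no Warburg characteristics)."""
    return cf.make_toy_network(cf.ToyNetworkSpec.uniform())


@pytest.fixture(scope="session")
def toy_sweep(toy):
    """A moderately fine crowding sweep of the default fixture."""
    return cf.growth_sweep(toy.model, toy.medium, toy.crowding, n_points=60)


@pytest.fixture()
def chain_model():
    """Fully determined linear chain with forced unit uptake."""
    mets = [cf.Metabolite("A_e", compartment="e"), cf.Metabolite("B_e", compartment="e")]
    rxns = [
        cf.Reaction("EX_A", {"A_e": -1}, -1.0, -1.0, is_exchange=True),
        cf.Reaction("CONV", {"A_e": -1, "B_e": 1}, 0.0, 10.0),
        cf.Reaction("EX_B", {"B_e": -1}, 0.0, 10.0, is_exchange=True),
    ]
    return cf.MetabolicModel(mets, rxns, biomass_reaction_id="EX_B")
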