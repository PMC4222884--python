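import pytest

from cljflux.core_model import CoreModelConfig, build_core_model
from cljflux.model import Metabolite, Reaction, build_model


@pytest.fixture(scope="session")
def core_model():
    """Default (NADP-hydrogenase) core reconstruction."""
    return build_core_model()


@pytest.fixture(scope="session")
def core_model_nad():
    return build_core_model(CoreModelConfig(hydrogenase_cofactor="nad"))


@pytest.fixture(scope="session")
def metabolite_table(core_model):
    return {m.id: m for m in core_model.metabolites}


def make_chain_model(uptake_cap=5.0):
    """EX_A(lb=-cap) -> A->B -> EX_B, objective EX_B."""
    mets = [
        Metabolite(id="a_e", compartment="e", formula={"C": 1}),
        Metabolite(id="b_e", compartment="e", formula={"C": 1}),
    ]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_e": -1.0}, lower_bound=-uptake_cap,
                 upper_bound=0.0, is_exchange=True),
        Reaction(id="AB", stoichiometry={"a_e": -1.0, "b_e": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="EX_b", stoichiometry={"b_e": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, is_exchange=True),
    ]
    return build_model(mets, rxns, objective_id="EX_b")


def make_parallel_model(cap=4.0):
    """Two equivalent internal paths from one source to one sink."""
    mets = [
        Metabolite(id="a_e", compartment="e", formula={"C": 1}),
        Metabolite(id="m_c", compartment="c", formula={"C": 1}),
        Metabolite(id="b_e", compartment="e", formula={"C": 1}),
    ]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_e": -1.0}, lower_bound=-cap,
                 upper_bound=0.0, is_exchange=True),
        Reaction(id="IN", stoichiometry={"a_e": -1.0, "m_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="P1", stoichiometry={"m_c": -1.0, "b_e": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="P2", stoichiometry={"m_c": -1.0, "b_e": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="EX_b", stoichiometry={"b_e": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, is_exchange=True),
    ]
    return build_model(mets, rxns, objective_id="EX_b")
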