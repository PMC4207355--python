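import pytest

from coreflux.gpr import parse_gpr
from coreflux.network import MetabolicNetwork, MetaboliteRecord, ReactionRecord
from coreflux.synthetic import FixtureSpec, figure_cycle_fixtures, make_toy_network


@pytest.fixture
def chain_network():
    """EX_A(-10..0) -> transport -> chain -> biomass; max biomass 10."""
    return make_toy_network(FixtureSpec(n_branches=1, branch_length=2, trunk_length=0))


@pytest.fixture
def branched_network():
    return make_toy_network(
        FixtureSpec(n_branches=2, branch_length=2, trunk_length=1, seed=7)
    )


@pytest.fixture(scope="session")
def cycle_fixtures():
    return figure_cycle_fixtures()


@pytest.fixture
def kinase_metabolites():
    """Real formulas for a glucose + ATP -> G6P + ADP + H+ balance check."""
    records = [
        MetaboliteRecord("glc", formula={"C": 6, "H": 12, "O": 6}, charge=0),
        MetaboliteRecord("atp", formula={"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, charge=-4),
        MetaboliteRecord("g6p", formula={"C": 6, "H": 11, "O": 9, "P": 1}, charge=-2),
        MetaboliteRecord("adp", formula={"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, charge=-3),
        MetaboliteRecord("h", formula={"H": 1}, charge=1),
        MetaboliteRecord("h2o", formula={"H": 2, "O": 1}, charge=0),
    ]
    return {m.id: m for m in records}


@pytest.fixture
def hexokinase(kinase_metabolites):
    return ReactionRecord(
        "HEX", {"glc": -1.0, "atp": -1.0, "g6p": 1.0, "adp": 1.0, "h": 1.0}, 0.0, 1000.0
    )


@pytest.fixture
def gpr_samples():
    return {
        "complex": parse_gpr("CAC0109 and CAC0110"),
        "isozymes": parse_gpr("CAC2391 or CAC3020"),
        "single": parse_gpr("CAC0316"),
        "nested": parse_gpr("(a and b) or c"),
    }
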