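import pytest

from oleoflux.gem_core import Gene, MetabolicModel, Metabolite, Reaction
from oleoflux.synthetic_data import ToyCoreSpec, make_toy_core_model


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Linear chain: R1 supplies A (bounded at 10), R2: A→B, R3 drains B."""
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite("A", compartment="c"),
            Metabolite("B", compartment="c"),
        ],
        reactions=[
            Reaction("R1", {"A": 1.0}, lower_bound=0.0, upper_bound=10.0,
                     kind="exchange"),
            Reaction("R2", {"A": -1.0, "B": 1.0}, lower_bound=0.0,
                     upper_bound=1000.0),
            Reaction("R3", {"B": -1.0}, lower_bound=0.0, upper_bound=1000.0,
                     kind="demand"),
        ],
        objective_reaction="R3",
    )


@pytest.fixture
def branched_model() -> MetabolicModel:
    """Two routes with biomass yields 0.5 and 0.8 sharing an uptake of 10."""
    model, record = make_toy_core_model(
        ToyCoreSpec(uptake_bound=10.0, yields=(0.5, 0.8))
    )
    model.analytic_record = record  # stashed for convenience in tests
    return model


@pytest.fixture
def product_model():
    """Toy core with the planted product branch (coupling 2)."""
    return make_toy_core_model(
        ToyCoreSpec(include_product_branch=True, coupling=2.0)
    )


@pytest.fixture
def five_reaction_model() -> MetabolicModel:
    """Round-trip fixture exercising GPRs, kinds, formulas and annotations."""
    return MetabolicModel(
        id="fixture5",
        metabolites=[
            Metabolite("glc_e", name="glucose", compartment="e",
                       formula={"C": 6, "H": 12, "O": 6},
                       annotations={"kegg": "C00031"}),
            Metabolite("glc_c", compartment="c"),
            Metabolite("pyr_c", name="pyruvate", compartment="c"),
        ],
        reactions=[
            Reaction("EX_glc_e", {"glc_e": -1.0}, lower_bound=-10.0,
                     upper_bound=1000.0, kind="exchange"),
            Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, lower_bound=0.0,
                     kind="transport", gpr="g1"),
            Reaction("GLYC", {"glc_c": -1.0, "pyr_c": 2.0}, lower_bound=0.0,
                     gpr="(g2 and g3) or g4",
                     annotations={"ec": "1.2.3.4"}),
            Reaction("PYRrev", {"pyr_c": -1.0, "glc_c": 0.5},
                     lower_bound=-1000.0, upper_bound=1000.0),
            Reaction("BIOMASS", {"pyr_c": -1.0}, lower_bound=0.0,
                     kind="biomass"),
        ],
        genes=[Gene("g1"), Gene("g2"), Gene("g3"), Gene("g4")],
        objective_reaction="BIOMASS",
    )
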