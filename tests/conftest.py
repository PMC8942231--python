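import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from commitgf.model_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)


def chain_model(model_id: str = "chain", uptake: float = 10.0) -> MetabolicModel:
    """Linear toy cell: EX_A (uptake) -> transport -> A->B -> biomass(B)."""
    m = MetabolicModel(id=model_id)
    for mid, comp in [("A", "e"), ("A", "c"), ("B", "c")]:
        m.add_metabolite(Metabolite(mid, comp))
    m.add_reaction(Reaction("EX_A", {("A", "e"): -1.0}, -uptake, DEFAULT_BOUND,
                            kind="exchange"))
    m.add_reaction(Reaction("T_A", {("A", "e"): -1.0, ("A", "c"): 1.0},
                            0.0, DEFAULT_BOUND, kind="transport"))
    m.add_reaction(Reaction("R_AB", {("A", "c"): -1.0, ("B", "c"): 1.0},
                            0.0, DEFAULT_BOUND))
    m.add_reaction(Reaction("BIO", {("B", "c"): -1.0}, 0.0, DEFAULT_BOUND,
                            kind="biomass"))
    m.biomass_id = "BIO"
    return m


@pytest.fixture
def chain():
    return chain_model()


@pytest.fixture(scope="session")
def two_member_community():
    """2-member community with one planted cross-feeding edge."""
    from commitgf.synthetic import CommunitySpec, generate_community

    return generate_community(
        CommunitySpec(n_members=2, core_pathway_length=4, n_cross_feeding=1, seed=1)
    )
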