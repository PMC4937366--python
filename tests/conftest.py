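import pytest

from paleoproof import damage as dmg
from paleoproof import lineage as lin
from paleoproof import molecule as mol
from paleoproof import simulate as sim


@pytest.fixture(scope="session")
def panel():
    """Standard lineage panel: 2 kb genome, 10 sites/branch, 10 pairwise."""
    return sim.generate_panel(seed=1, genome_length=2000, n_sites_per_branch=10, n_pairwise_sites=10)


@pytest.fixture(scope="session")
def branch_sites(panel):
    return lin.find_diagnostic_sites(panel, lin.BRANCH_SPECIFIC)


@pytest.fixture(scope="session")
def damaged_collection(panel):
    """10k pure-endogenous modern-human fragments, p_max=0.3, p_base=0.01."""
    model = sim.DamageModel(p_max=0.3, p_base=0.01)
    fragset = sim.simulate_fragments(panel, "modern_human", 10_000, model, 0.0, seed=11)
    return mol.collection_from_fragmentset(fragset, deduplicate_fragments=False)


@pytest.fixture(scope="session")
def mixture_collection(panel):
    """50/50 damaged endogenous / undamaged contaminant mixture."""
    model = sim.DamageModel(p_max=0.3, p_base=0.01)
    fragset = sim.simulate_fragments(panel, "modern_human", 10_000, model, 0.5, seed=12)
    return mol.collection_from_fragmentset(fragset, deduplicate_fragments=False)


@pytest.fixture(scope="session")
def damaged_profile(damaged_collection):
    return dmg.damage_profile(damaged_collection, K=15)
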