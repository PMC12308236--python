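import numpy as np
import pytest

from phyloprev import (
    MCMCConfig,
    ModelSpec,
    PrevalenceDataset,
    SimulationConfig,
    simulate_dataset,
    simulate_yule_tree,
    tree_from_newick_string,
)

THREE_TIP = "((A:0.5,B:0.5):0.5,C:1);"


@pytest.fixture
def three_tip_tree():
    return tree_from_newick_string(THREE_TIP)


@pytest.fixture
def yule10():
    return simulate_yule_tree(10, seed=42)


@pytest.fixture
def fast_mcmc():
    return MCMCConfig(iterations=600, burn_in=200, thin=1, chains=2, seed=7)


@pytest.fixture
def small_sim():
    """30-species simulated tree + dataset with a real mass effect."""
    cfg = SimulationConfig(
        n_species=30, beta_mass=0.8, sigma_phylo=0.5, structure_param=2.0, seed=11
    )
    return simulate_dataset(cfg)


@pytest.fixture
def mass_spec():
    return ModelSpec(response="neoplasia", predictors=("log10_mass",))


def make_dataset(S=10, seed=0, n=30, response="neoplasia", p=0.1):
    """Small hand-rolled dataset on no particular tree."""
    rng = np.random.default_rng(seed)
    k = rng.binomial(n, p, size=S)
    return PrevalenceDataset(
        species=[f"sp{i + 1:03d}" for i in range(S)],
        n_necropsies=np.full(S, n),
        k_cases={response: k},
        log10_mass=rng.normal(0.5, 1.0, S),
        log10_longevity=rng.normal(2.3, 0.3, S),
    )
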