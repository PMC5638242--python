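import pytest

from polyflow.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Compact zero-noise scenario for fast unit tests."""
    config = ScenarioConfig(
        n_proteins=60,
        n_tfs=8,
        n_genes=30,
        n_inhibitors=10,
        n_planted_synergizers=2,
        n_planted_genetic_hits=6,
        n_planted_paths=4,
        path_length=2,
        noise_sd_lu=0.0,
        seed=11,
    )
    return generate_scenario(config)


@pytest.fixture(scope="session")
def study_scenario():
    """Zero-noise scenario at the reference study size (200 proteins, 20 TFs,
    100 genes, 8 planted paths)."""
    return generate_scenario(ScenarioConfig(seed=1, noise_sd_lu=0.0))


@pytest.fixture(scope="session")
def study_inputs(study_scenario):
    from helpers import derive_inputs

    return derive_inputs(study_scenario)


@pytest.fixture(scope="session")
def study_assessment(study_scenario, study_inputs):
    """Node assessment with the full 100 randomizations per commodity."""
    from polyflow.flow import FlowParams
    from polyflow.significance import assess_nodes

    _, kin, gen, de = study_inputs
    table, real = assess_nodes(
        kin,
        gen,
        de,
        study_scenario.interactome,
        study_scenario.regulatory_edges,
        FlowParams(gamma=20.0),
        n_random=100,
        seed=3,
    )
    return table, real
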