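import pytest

from dmrlink.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression_tables,
    simulate_methylome_pair,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(sim_config):
    """One full synthetic study: annotation, methylomes, truth, DE tables."""
    ann = simulate_annotation(sim_config)
    rec_a, rec_b, truth = simulate_methylome_pair(sim_config, ann)
    deg, demirna = simulate_expression_tables(sim_config, truth, ann)
    return {
        "config": sim_config,
        "annotation": ann,
        "rec_a": rec_a,
        "rec_b": rec_b,
        "truth": truth,
        "deg": deg,
        "demirna": demirna,
    }


@pytest.fixture(scope="session")
def called_dmrs(study):
    from dmrlink.dmr import call_dmrs

    return call_dmrs(study["rec_a"], study["rec_b"])
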