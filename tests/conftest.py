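import pytest

from haploscan.simulate import (
    SimulationConfig,
    emit_individual_callsets,
    emit_pooled_callset,
    frequency_panel,
    generate_truth,
    known_catalog,
)


@pytest.fixture(scope="session")
def demo_config():
    """Error-free study-design defaults: 4 haplotype SNVs among 1000 population SNVs."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def demo_truth(demo_config):
    return generate_truth(demo_config)


@pytest.fixture(scope="session")
def demo_callsets(demo_truth, demo_config):
    return emit_individual_callsets(demo_truth, demo_config)


@pytest.fixture(scope="session")
def demo_pool(demo_truth, demo_config):
    return emit_pooled_callset(demo_truth, demo_config)


@pytest.fixture(scope="session")
def demo_panel(demo_truth):
    return frequency_panel(demo_truth)


@pytest.fixture(scope="session")
def demo_catalog(demo_truth):
    return known_catalog(demo_truth)
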