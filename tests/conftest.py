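import pytest

from orf15asm.simulate import (
    RepeatModel,
    SimulationConfig,
    default_coordinate_map,
    simulate_sample,
    spike_standard_truthsets,
    synthesize_reference,
)


@pytest.fixture(scope="session")
def model():
    return RepeatModel()


@pytest.fixture(scope="session")
def ref(model):
    return synthesize_reference(model, seed=1)


@pytest.fixture(scope="session")
def cmap(ref, model):
    return default_coordinate_map(ref, model)


@pytest.fixture(scope="session")
def catalogue(ref):
    return spike_standard_truthsets(ref)


@pytest.fixture(scope="session")
def clean_sample(ref, catalogue):
    """A deep, variant-free sample shared by assembly/selection tests."""
    cfg = SimulationConfig(seed=99, coverage=1000)
    return simulate_sample(ref, catalogue["no_variant"], cfg)
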