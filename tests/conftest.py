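import pytest

from c1flux.curation import (
    apply_curation,
    base_curation_recipe,
    serine_cycle_recipe,
)
from c1flux.synth import ToyModelSpec, gen_core_model, gen_toy_model


@pytest.fixture(scope="session")
def core_model():
    """Uncurated core-metabolism network (genome-scale stand-in)."""
    return gen_core_model()


@pytest.fixture(scope="session")
def base_curated(core_model):
    """Core network after the C1-auxotroph curation recipe."""
    return apply_curation(core_model, base_curation_recipe())


@pytest.fixture(scope="session")
def serine_model(base_curated):
    """Core network after base + serine-cycle recipes."""
    return apply_curation(base_curated, serine_cycle_recipe())


@pytest.fixture
def toy_factory():
    """Factory for analytic toy models: toy_factory(b=...) -> (model, answers)."""

    def make(**kwargs):
        return gen_toy_model(ToyModelSpec(**kwargs))

    return make
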