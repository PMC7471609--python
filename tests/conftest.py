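import pytest

from fluxkit.conditions import apply_bound_overrides, set_condition
from fluxkit.fixtures import ToyModelSpec, make_toy_core_model, toy_condition


@pytest.fixture(scope="session")
def chain_model():
    return make_toy_core_model(ToyModelSpec())


@pytest.fixture(scope="session")
def redox_model():
    return make_toy_core_model(ToyModelSpec(include_redox=True))


@pytest.fixture(scope="session")
def cycle_model():
    return make_toy_core_model(ToyModelSpec(include_cycle=True))


@pytest.fixture(scope="session")
def chain_condition(chain_model):
    return toy_condition(chain_model)


@pytest.fixture(scope="session")
def redox_condition(redox_model):
    return toy_condition(redox_model)


@pytest.fixture(scope="session")
def configured_chain(chain_model, chain_condition):
    """Chain toy under the standard batch condition (uptake <= 10)."""
    return set_condition(chain_model, chain_condition)


@pytest.fixture(scope="session")
def configured_redox(redox_model, redox_condition):
    return set_condition(redox_model, redox_condition)


@pytest.fixture(scope="session")
def pinned_redox(configured_redox):
    """Redox toy with uptake and growth pinned (unique interior state)."""
    return apply_bound_overrides(
        configured_redox,
        {"EX_cellb_e": (-10.0, -10.0), "BIOMASS_CELLOBIOSE": (2.0, 2.0)},
    )
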