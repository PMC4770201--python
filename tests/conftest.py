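import pytest

from dmfsynth.workbench import make_pop_fixture, make_azurin_fixture
from dmfsynth.mcad_planner import plan_library
from dmfsynth.dmf_protocol import compile_protocol


@pytest.fixture(scope="session")
def pop_fixture():
    return make_pop_fixture(seed=1)


@pytest.fixture(scope="session")
def pop_plan(pop_fixture):
    return pop_fixture.plan()


@pytest.fixture(scope="session")
def azurin_spec():
    return make_azurin_fixture(seed=1)


@pytest.fixture(scope="session")
def azurin_plan(azurin_spec):
    return plan_library(azurin_spec)


@pytest.fixture(scope="session")
def pop_protocol(pop_plan):
    return compile_protocol(pop_plan)


@pytest.fixture(scope="session")
def azurin_protocol(azurin_plan):
    return compile_protocol(azurin_plan)
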