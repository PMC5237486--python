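from fractions import Fraction

import pytest

from donorgap import builtin_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def base(scenarios):
    return scenarios["base"]


@pytest.fixture(scope="session")
def best(scenarios):
    return scenarios["best"]


@pytest.fixture(scope="session")
def worst(scenarios):
    return scenarios["worst"]


@pytest.fixture(scope="session")
def base_supply_stage_values(base):
    return tuple(p.value for p in base.supply.stages)
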