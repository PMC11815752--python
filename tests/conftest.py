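import pytest

from residose.diet import Diet, Portion, bundled_diet, bundled_food_table
from residose.mrl import bundled_registry


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


@pytest.fixture(scope="session")
def foods():
    return bundled_food_table()


@pytest.fixture(scope="session")
def standard_diet():
    """The bundled 453 g one-day diet (milk 200 g, egg 53 g, chicken 100 g,
    cod 100 g) for a 60 kg adult, plus its PRI."""
    diet, pri = bundled_diet()
    return diet, pri


@pytest.fixture()
def tiny_diet():
    return Diet(portions=(Portion("milk", 100.0),), consumer_bw=60.0)
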