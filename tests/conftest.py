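import pytest

from hfcea import ParameterSet, synthesize_life_table


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def synth_table():
    return synthesize_life_table()
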