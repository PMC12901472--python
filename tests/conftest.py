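import pytest

import adcea


@pytest.fixture(scope="session")
def table1():
    """The shipped default model configuration."""
    return adcea.default_parameters()


@pytest.fixture(scope="session")
def base_results(table1):
    """Deterministic base case of the shipped model (results, increments)."""
    return adcea.base_case(table1)
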