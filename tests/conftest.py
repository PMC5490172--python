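import pytest

from marinerscan import simulate as sim


@pytest.fixture(scope="session")
def specs():
    return sim.default_element_specs()


@pytest.fixture(scope="session")
def macro_element(specs):
    return sim.build_autonomous_element(specs["Macromar1"])


@pytest.fixture(scope="session")
def planted_macro(specs):
    """(parent with BPEE windows, (del_start, del_end))."""
    return sim._planted_parent(specs["Macromar1"], "BPEE", seed=0)
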