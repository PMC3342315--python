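import pytest

from regnet import synthetic_data as sd


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at default conditions, shared across tests."""
    return sd.simulate(seed=3)


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(n_genes=300)
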