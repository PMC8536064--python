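import pytest

from pepscreen import (
    SyntheticConfig,
    default_hydrophobicity,
    default_residue_pi,
    default_thermolysin,
)


@pytest.fixture(scope="session")
def hydro_scale():
    return default_hydrophobicity()


@pytest.fixture(scope="session")
def pi_scale():
    return default_residue_pi()


@pytest.fixture(scope="session")
def thermolysin():
    return default_thermolysin()


@pytest.fixture
def config():
    return SyntheticConfig(seed=12345, n_proteins=30)
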