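import pytest

from mihatyper import (
    CallingConfig,
    NoiseConfig,
    default_frequency_fixture,
    load_default_panel,
)


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def freqs():
    return default_frequency_fixture()


@pytest.fixture
def cfg():
    return CallingConfig()


@pytest.fixture
def noise_free():
    """Deterministic signal model: no scatter, no artifacts."""
    return NoiseConfig(cq_sd=0.0, plateau_rfu_sd=0.0)


@pytest.fixture(scope="session")
def ha1(panel):
    """A representative SNP locus (ref G, alt A, immunogenic A)."""
    return panel.locus("HA-1/A2")
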