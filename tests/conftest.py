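import pytest

from syntopy import build_observed_fixture, default_config, generate_assemblage


@pytest.fixture(scope="session")
def observed_network():
    return build_observed_fixture()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A default-condition synthetic assemblage (fixed seed)."""
    return generate_assemblage(default_config(seed=42))
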