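import pytest

from asarscan.simulate import demo_config, simulate_dataset


@pytest.fixture(scope="session")
def demo_dataset():
    """One simulated six-clone dataset shared across tests (read-only)."""
    return simulate_dataset(demo_config(seed=11))
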