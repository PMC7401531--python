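import pytest

from rccpipe import SimConfig, default_panel, normalize_runset, simulate_runset


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def clean_runset():
    """Default study-sized run set (16 animals x 3 times) with no effects."""
    runset, _ = simulate_runset(SimConfig(seed=1))
    return runset


@pytest.fixture(scope="session")
def normalized(clean_runset):
    return normalize_runset(clean_runset)
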