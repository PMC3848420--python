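import pytest

from lrrscan import default_patterns, generate, nlrc5_mimic


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture(scope="session")
def pattern_by_name(patterns):
    return {p.name: p for p in patterns}


@pytest.fixture(scope="session")
def mimic():
    """Synthetic NLRC5 stand-in (record, ground truth) at a fixed seed."""
    return generate(nlrc5_mimic(seed=1))
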