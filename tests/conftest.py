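import pytest

from lepusmito.synthgen import GenomeSimConfig, gen_mitogenome


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic genome + its ground truth (shared, read-only)."""
    return gen_mitogenome(GenomeSimConfig(seed=42, label="SYNFIX"))


@pytest.fixture(scope="session")
def genome(default_genome):
    return default_genome[0]


@pytest.fixture(scope="session")
def truth(default_genome):
    return default_genome[1]
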