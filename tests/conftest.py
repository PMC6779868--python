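import pytest

from seedscreen import enumerate_scenarios


@pytest.fixture(scope="session")
def diploid_default():
    """Default diploid scenario set (k=2 central cell, no BIII)."""
    return enumerate_scenarios(2, (2,))


@pytest.fixture(scope="session")
def diploid_extended():
    """Extended diploid set with tri-nucleate central cell and BIII hybrids."""
    return enumerate_scenarios(2, (2,), include_trinucleate=True, include_biii=True)
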