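import pytest

from castscan.scenarios import amplicon_scenario, lysate_scenario


@pytest.fixture(scope="session")
def amplicon():
    """(ref, site, donor) for the 4-kb amplicon locus fixture."""
    return amplicon_scenario()


@pytest.fixture(scope="session")
def lysate():
    """(ref, site, donor) for the 100-kb lysate-genome fixture."""
    return lysate_scenario()
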