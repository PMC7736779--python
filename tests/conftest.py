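import pytest

from asmdiff.simulate import (
    gen_genome_pair,
    gen_proteome_pair,
    gen_region_fixtures,
    gen_transcripts,
)


@pytest.fixture(scope="session")
def genome_sim():
    return gen_genome_pair(seed=11)


@pytest.fixture(scope="session")
def proteome_sim():
    return gen_proteome_pair(seed=11)


@pytest.fixture(scope="session")
def transcript_sim():
    return gen_transcripts(seed=11)


@pytest.fixture(scope="session")
def region_sim():
    return gen_region_fixtures(seed=11)
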