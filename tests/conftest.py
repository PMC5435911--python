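import pytest

from circends.align import KmerIndex
from circends.toy import toy_annotation, toy_genome


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def annotation(genome):
    return toy_annotation(genome)


@pytest.fixture(scope="session")
def index(genome):
    return KmerIndex(genome)
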