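import pytest

from unginminer import reference
from unginminer.io import GenomeRecord


@pytest.fixture(scope="session")
def ugi():
    """The genuine 84-residue PBS1/PBS2 Ugi protein."""
    return reference.load_ugi()


@pytest.fixture(scope="session")
def positives():
    """All bundled Ugi/SAUGI-type calibration positives."""
    return reference.load_ugi_saugi_positives()


@pytest.fixture
def tiny_genome():
    """A 9 nt genome with hand-computable six-frame structure."""
    return GenomeRecord(id="tiny", seq="ATGAAATAA")
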