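import pytest

import sepiapep
from sepiapep import motif, prohormone


@pytest.fixture(scope="session")
def fixture_precursors():
    """The packaged synthetic FLGa A/B precursor reconstructions."""
    return prohormone.read_precursors(sepiapep.packaged_precursor_fasta())


@pytest.fixture(scope="session")
def flga_peptides(fixture_precursors):
    """Named mature peptides excised from the FLGa A precursor."""
    prec = fixture_precursors[0]
    return prohormone.name_peptides(prohormone.excise_peptides(prec))


@pytest.fixture(scope="session")
def patterns():
    return motif.load_patterns()
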