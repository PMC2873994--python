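import pytest

from hlassp import load_default_panel, reactivity_matrix
from hlassp.panel_model import LOCI


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def matrices(panel):
    return {locus: reactivity_matrix(panel, locus) for locus in LOCI}


@pytest.fixture(scope="session")
def matrix_a(matrices):
    return matrices["HLA-A"]


@pytest.fixture(scope="session")
def matrix_b(matrices):
    return matrices["HLA-B"]


@pytest.fixture(scope="session")
def matrix_c(matrices):
    return matrices["HLA-C"]


TOY_PANEL = """\
locus\tHLA-A

[primers]
P1F01\tACGTACGTACGTAC[G]\tforward\t10-24
P2R01\tTTTTCCCCGGGGAA\treverse\t700-713

[probes]
PRF01\tFAM\tBHQ1\tACGTACGTACGTACGT\t30-45
PRT01\tTET\tBHQ1\tACACACACACACACAC\t750-765

[reactions]
HLA-A 001\tP1F01\tP2R01\tPRF01\tP2R01\tP1F01\tPRT01\tA*0101,A*0202
"""


@pytest.fixture
def toy_panel_text():
    return TOY_PANEL
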