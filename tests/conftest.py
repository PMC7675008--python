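import pytest

from neotad.intervals import GenomicInterval
from neotad.locus_model import parse_sv
from neotad.synthetic_data import MatrixGenParams, gen_locus, gen_sv_suite, gen_wt_matrix

# Printed breakpoint notations of the two fully specified disease alleles;
# the 700 kb window around them is the working reference extent.
NL_SV1_NOTATION = "chr17:57,291,905_57,518,137dup"
UK_SV2_NOTATION = "chr17:57,456,098-57,468,960delins57,275,839_57,559,114inv"
CORE_1BASED = (57_499_214, 57_510_765)


@pytest.fixture(scope="session")
def ext17():
    return GenomicInterval("chr17", 57_000_000, 57_700_000)


@pytest.fixture(scope="session")
def nl_sv1(ext17):
    return parse_sv(NL_SV1_NOTATION, ext17, sv_id="NL-SV1")


@pytest.fixture(scope="session")
def uk_sv2(ext17):
    return parse_sv(UK_SV2_NOTATION, ext17, sv_id="UK-SV2")


@pytest.fixture(scope="session")
def locus():
    return gen_locus(0)


@pytest.fixture(scope="session")
def suite(locus):
    return gen_sv_suite(locus)


@pytest.fixture(scope="session")
def wt_matrix(locus):
    return gen_wt_matrix(locus, MatrixGenParams(seed=0))


@pytest.fixture(scope="session")
def wt_expected(locus):
    """Noise-free wild-type matrix (beta/gamma structure, no Poisson)."""
    return gen_wt_matrix(locus, MatrixGenParams(noise="none"))
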