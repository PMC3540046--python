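import pytest

from hla2x2.cohort import Disease, SeroGroup
from hla2x2.fixtures import ra_cohort, se_stratified_cohort, sle_cohort, two_locus_cohort_drb1_0803
from hla2x2.residues import default_residue_map


@pytest.fixture(scope="session")
def ra():
    return ra_cohort()


@pytest.fixture(scope="session")
def ra_groups(ra):
    """(Ro+La-, Ro+La+, Ro-La-) RA cohorts."""
    return (
        ra.group(SeroGroup.RO_POS_LA_NEG),
        ra.group(SeroGroup.RO_POS_LA_POS),
        ra.group(SeroGroup.RO_NEG_LA_NEG),
    )


@pytest.fixture(scope="session")
def sle():
    return sle_cohort()


@pytest.fixture(scope="session")
def two_locus():
    return two_locus_cohort_drb1_0803()


@pytest.fixture(scope="session")
def se_cohort():
    return se_stratified_cohort()


@pytest.fixture(scope="session")
def rmap():
    return default_residue_map()
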