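import pytest

from allelequant.primer_design import DesignConstraints
from allelequant.synthetic_data import gen_allele_family

# Tm target for synthetic families: under the unified NN model at 50 mM
# Na+/500 nM primer, random 21-mers at the generator's 62% GC melt around
# 61-62 degC, so synthetic design uses 62 +/- 2.5 (the 66 degC default reflects
# the hotter Tm scale of the original wet-lab software).
SYNTH_CONSTRAINTS = dict(tm_target=62.0, tm_tol=2.5)


@pytest.fixture(scope="session")
def family():
    """Default synthetic family: 3 loci x 4 alleles x 1200 nt, seed 1."""
    return gen_allele_family(1)


@pytest.fixture(scope="session")
def clean_family():
    """No random SNPs: alleles differ only at their engineered sites."""
    return gen_allele_family(7, snp_rate=0.0)


@pytest.fixture()
def synth_constraints():
    return DesignConstraints(**SYNTH_CONSTRAINTS)
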