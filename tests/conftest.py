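import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coshort.meiosis import GenomeSpec, ParentGenome
from coshort.synth import make_variety_panel, make_vcf_fixture

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def parent12():
    """Fully heterozygous diploid parent, 12 chromosomes, 25 markers each."""
    return ParentGenome.fully_heterozygous(GenomeSpec.uniform(n_chrom=12, n_markers=25))


@pytest.fixture(scope="session")
def panel_sim():
    return make_variety_panel(seed=5)


@pytest.fixture(scope="session")
def vcf_sim():
    return make_vcf_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
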