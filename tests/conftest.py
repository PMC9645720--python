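import numpy as np
import pytest

from oriscape.origins_io import Genome, OriginDomainSet, OriginRecord
from oriscape.synthetic_data import SyntheticStudy, small_config


@pytest.fixture(scope="session")
def small_study():
    """One shared small synthetic study (2-Mb genome, 40 origins)."""
    return SyntheticStudy(small_config(), seed=1)


@pytest.fixture(scope="session")
def small_domainset(small_study):
    return small_study.domainset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_genome(rng):
    """A 100-kb single-chromosome genome for targeted unit tests."""
    seq = "".join(rng.choice(list("ACGT"), size=100_000))
    return Genome({"chr1": seq})


@pytest.fixture
def single_origin_domainset():
    """One origin with midpoint 50,000 on chr1, default 200-window frame."""
    origin = OriginRecord("chr1", 49_500, 50_500)
    return OriginDomainSet([origin])
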